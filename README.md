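# fragilenet

Closed-loop detection and state-feedback stabilization of a *fragile*
stochastic neuronal network.

A small excitatory/inhibitory network of binary neurons is simulated as a
continuous-time Markov jump process (event-driven Gillespie algorithm). The
network is parameterized to sit just below its stability boundary; a
minimum-energy perturbation of a single node's inbound functional
connections tips it into an unstable "seizure" mode in which the most
fragile (inhibitory) node falls silent and disinhibits the rest of the
network. A two-mode Gaussian-emission detector watches that node's windowed
firing rate and thresholds the derivative of a cumulative likelihood ratio
to declare instability; a state-feedback gain on the fragile node then
cancels the perturbation and the loop switches off once the rate has sat
inside a ±2 SD stable band for 500 ms.

## Layout

| module                    | contents |
|---------------------------|----------|
| `fragilenet.network`      | binary-neuron model, clamped-tanh response, exact event-driven simulation |
| `fragilenet.fragility`    | mean-field fixed point, functional connectivity (Jacobian) and input matrix, minimum-norm single-row destabilizing perturbations, per-node fragility ranking, stable/unstable mode matrices |
| `fragilenet.detector`     | windowed normalized firing-rate estimator, Gaussian emission MLE, likelihood-ratio statistics, threshold calibration, stability re-detection, online detector |
| `fragilenet.control`      | linear-model gain `K = -B^-1 Δ` and nonlinear-model gain `K = -Δ`, control input `u = σKx + h` |
| `fragilenet.loop`         | closed-loop orchestration, episode metrics (detection delay, stable-mode delay, first stable firing rate), benchmark reports |
| `fragilenet.generator`    | rejection-sampled 6-node / 14-connection fixtures with a designated inhibitory fragile node (node 4) and verified disinhibition |
| `fragilenet.io` / `.cli`  | CSV/JSON/YAML artifacts, manifests, command-line interface |

## CLI

```sh
fragilenet generate --seed 1 --out out/net
fragilenet calibrate --seed 10 --network out/net/network.json --out out/calib
fragilenet simulate  --seed 5  --network out/net/network.json --mode unstable --target 200 --out out/sim
fragilenet run-closed-loop --seed 3 --network out/net/network.json \
    --calibration out/calib --variant nonlinear --duration-s 120 --out out/loop
fragilenet benchmark --seed 7 --network out/net/network.json \
    --calibration out/calib --detections 100 --out out/bench
```

Every command writes a `manifest.json` (seed, config hash, versions) so runs
reproduce bit-identically. A YAML/JSON `--config` can override generator,
detector and episode settings (e.g. `episode_targets: [200.0]`).

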