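# qtaimnet

Prediction of local real-space chemical descriptors — per-atom (1P)
quantities such as QTAIM charges and localization indices, and per-pair
(2P) quantities such as delocalization indices and IQA interaction
energies — from molecular geometries, using continuous-filter message
passing with pooling-free atom-wise and pair-wise readout heads. The
package also provides:

- exact electron-count and energy **sum-rule bookkeeping** (`q = Z - N`,
  `lambda = N - sigma^2`, `delta = -2 cov`, `N = sum(lambda) + sum(delta)`,
  `E = sum(E_intra) + sum(E_inter)`) and a reconstruction-based
  **uncertainty score** for predictions;
- a **surrogate data generator** producing random molecules with physically
  consistent labels (electronegativity-equalization charges, exponentially
  decaying bond orders, Coulomb + Born-Mayer pair energies) that are closed
  under all sum rules by construction, plus scripted host-guest binding
  trajectories with ground-truth event tables;
- a **trajectory analysis layer** that aggregates raw pair predictions into
  group-group delocalization time series, detects binding events (local
  delocalization maxima / center-of-mass distance minima), matches
  electronic and geometric events within a +-10 fs tolerance, and ranks the
  dominant atom-pair contributions behind each contact.

Everything is pure NumPy/SciPy: the network forward pass, reverse-mode
gradients, and the Adam optimizer are implemented in-package, so training
and inference are deterministic given the seeds in the configs.

## Layout

| Module | Contents |
| --- | --- |
| `qtaimnet.chemsys` | `Molecule`, canonical pair enumeration, XYZ + JSONL dataset I/O |
| `qtaimnet.representation` | Gaussian distance expansion, cosine cutoff, interaction blocks → per-atom environment matrix |
| `qtaimnet.local_readout` | AIMwise / ElementalAIMwise / ElementalPairAIMwise heads, pair-type encoding, symmetrized 2P evaluation, checkpoints |
| `qtaimnet.qct_properties` | sum-rule math, residual reports, reconstruction uncertainty |
| `qtaimnet.training` | splits, composite local+global loss, training loop, MAE/RMSE evaluation |
| `qtaimnet.surrogate_data` | labeled random molecules and scripted binding trajectories |
| `qtaimnet.xcai_analysis` | group delocalization series, bin averaging, event detection/matching, pair-contribution ranking |

## CLI

```bash
# labeled surrogate dataset (newline-delimited JSON) + sum-rule audit
qtaimnet generate --preset chon --n 2000 --seed 1 --out data.jsonl
qtaimnet check-sumrules --dataset data.jsonl

# training and evaluation
qtaimnet train --data data.jsonl --property q --mode ElementalAIMwise \
    --seed 1 --out charge.ckpt --log train.csv
qtaimnet evaluate --model charge.ckpt --data data.jsonl --report report.json

# inference on XYZ structures (2P models can restrict the emitted pairs)
qtaimnet predict --model delta.ckpt --xyz structures.xyz --out preds.jsonl \
    --pairs-within 4.0

# scripted binding trajectory + group-delocalization event analysis
qtaimnet generate-trajectory --frames 1000 --events events.yaml \
    --out traj.xyz --truth truth.json
qtaimnet analyze --model delta.ckpt --traj traj.xyz \
    --groups traj.xyz.groups.json --pairs guest:A,guest:B \
    --bin 20 --tol 10 --out report/
```

`events.yaml` is a list of scheduled contacts, e.g.

```yaml
- {kind: approach, group: A, start: 100, contact: 310, end: 500}
- {kind: rotate,   group: B, start: 850, contact: 930, end: 990}
```

`train --config cfg.yaml` accepts a YAML file with `representation`
(feature width `n`, `n_interactions`, `r_cut`, `n_rbf`, `seed`) and
`training` (loss weights, batch size, learning rate, epochs, splits)
sections; defaults are sized for single-CPU desk-scale runs.

## Units

Electron-count properties are in electrons, energies in hartree (a.u.);
coordinates and distances in angstrom. Energy reports can be converted with
1 a.u. = 627.5 kcal/mol (`EvalReport.in_kcalmol`). Surrogate energy
formulas take distances in angstrom as-is; the generator is a qualitative
stand-in, not a quantum-chemical method.
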