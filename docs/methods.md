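# Methods

This note describes the model implemented by `fedct`, the assumptions behind
its synthetic data generator, the default parameters and why they were
chosen, and the numerical choices and limitations of the implementation.

## 1. Problem setting

Low-dose CT trades patient dose for measurement quality. Three canonical
dose-reduction regimes are modelled:

* **low-mAs** — the tube current is reduced, so each detector reading is
  photon-starved and the log-sinogram is noisy;
* **sparse-view** — only a uniform subset of projection views is acquired;
* **limited-angle** — views are restricted to a contiguous angular block.

Different sites (clients) operate different scanners, protocols and patient
populations, so their data are non-IID in geometry, degradation type and
anatomy. Sharing raw data is prohibited; the package studies collaborative
training in which **only model parameters of a designated shared model ever
leave a client**.

## 2. Reconstruction models

### Dual-domain client model

Each client owns a dual-domain reconstruction network:

* a **sinogram network** (1×3 kernels along the detector axis, group
  normalisation, leaky ReLU, residual units with channel attention, and a
  zero-initialised residual head) that restores the measured sinogram;
* a fixed, differentiable **back-projection operator** mapping the sinogram
  domain to the image domain (see §5);
* an **image network** (a small U-Net with strided downsampling,
  nearest-neighbour upsampling and a zero-initialised residual head) that
  removes residual artefacts.

Because every learned block is a residual branch starting at zero, the whole
model is exactly the analytic reconstruction operator at initialisation;
training only ever refines it.

### Condition-prompted shared model

A lightweight **shared model** (stacked 7×7 convolutional enhancement units
with spatial attention and a zero-initialised residual head) operates purely
in the image domain. Its feature maps are modulated per channel as
`f~ = V1 * f + V2`, where `(V1, V2)` are produced by a **prompt network**
(three fully connected layers per modulated unit) from a fixed 13-slot
**condition vector** encoding the acquisition: geometry scale (distances,
view/bin counts, spacings, all log- or range-normalised to [0, 1]), a
one-hot degradation type, and the degradation's strength (photon intensity,
kept-view fraction, or angular span fraction). The prompt head is
initialised to the identity (`V1 = 1`, `V2 = 0`), so prompting is a no-op
until trained. The shared model is roughly an order of magnitude lighter
than the dual-domain model, which keeps the communication cost of federation
low.

### Metamodel

The server holds a **metamodel** with the same architecture as the shared
model, trained on a server-side **metadata pool**: paired (degraded
reconstruction, clean image) examples spanning many protocols and regions.
It acts as a data-grounded anchor during aggregation.

## 3. Training objectives

Per round each client runs synchronized **mutual learning** between its
dual-domain model `Phi_dual` and the broadcast shared model `Phi_m`:

* client objective: `||y* - Phi_dual(x)||^2 + eps_k * TV +
  alpha_k * Huber(Phi_dual, Phi_m)`;
* shared objective: `||y* - Phi_m(y~)||^2 + eps_k * TV +
  (1 - alpha_k) * Huber(Phi_m, Phi_dual)`.

The Huber distance (`delta = 0.1`) makes distillation robust to early
outliers; mutual targets are detached so each model treats the other's
output as a constant. For **unpaired** clients (no clean references) the
fidelity term is dropped and the anisotropic total-variation prior is
enabled (`eps_k = 0.1`); paired clients use `eps_k = 0`. `alpha_k = 0.5`
balances the two directions.

The server then updates the metamodel on the metadata pool (plain MSE) and
aggregates:

```
theta_global = omega_c * theta_meta + (1 - omega_c) * sum_k omega_k * theta_k
```

with `omega_c = 0.55` and uniform `omega_k` by default. The aggregate is
broadcast to all clients and becomes the next round's metamodel. Uploads are
validated: any parameter whose name marks it as part of the sinogram or
image network raises a hard `PrivacyViolation`.

### Modes

`fedm2ct` (full), `no_fmdl` (no metamodel anchor, `omega_c = 0`),
`no_cpml` (no mutual learning or prompting), `no_prompt` (no conditional
prompting), and `fedavg_baseline` (plain parameter averaging with both
modules off).

### Diagnostics

The **weight divergence** `sum_l ||theta_FL^l - theta_local^l|| /
||theta_local^l||` is computed against per-client *shadow* models trained
with the identical schedule and batches but never aggregated, so the metric
isolates the effect of aggregation.

Cohort heterogeneity is quantified by the KL divergence of pooled HU
histograms (window [−1000, 2000] HU, 256 bins, additive smoothing 1e−10,
nats) and by gray-level co-occurrence (GLCM) texture features (32 levels,
distance 1, angles 0° and 90°; contrast, homogeneity, energy, correlation)
with Wilcoxon rank-sum p-values per feature.

## 4. Synthetic cohort generator

Clinical data are replaced by procedural piecewise-constant phantoms in
Hounsfield units, one family per anatomical region code:

1. **brain** — a round body with a high-attenuation rim and low-contrast
   inner structures;
2. **abdomen** — an elliptical body with mid-contrast inserts;
3. **chest** — an elliptical body with two lung-like low-attenuation regions
   plus soft-tissue/bone inserts;
4. **phantom** — a quality-assurance style disc with up to six inserts drawn
   from a fixed HU palette, giving at most eight distinct values per image.

Structures are ellipses with randomised count (3–7), position (constrained
to lie inside the body), size and value; all randomness flows through
explicit seeds. The generator emulates the *statistical situation* of a
multi-site cohort — different HU histograms and textures per region — not
anatomical realism. Measurements are produced by forward-projecting the
phantom with the client's geometry and degrading the ideal sinogram with the
client's protocol; low-mAs noise uses transmitted counts
`Poisson(I0 * exp(-p))` with a one-photon floor, so the log-domain noise
variance is approximately `exp(p)/I0`.

Per client, images are split 85/5/10 into train/val/test; unpaired clients
lose the clean references of their training split only.

## 5. Numerical choices

* **Projector.** A Joseph-style interpolating line integral is materialised
  once per geometry as a `scipy.sparse` CSR matrix (parallel and flat-panel
  fan beams). Its exact transpose is the adjoint used both for
  back-projection and for gradient propagation through the operator, so the
  dot-product identity holds to float round-off.
* **FBP.** The band-limited spatial-domain ramp kernel
  (`h[0] = 1/(4 ds^2)`, `h[odd] = -1/(pi k ds)^2`) is transformed to the
  frequency domain, apodised (ram-lak, shepp-logan or hamming window) and
  applied by zero-padded FFT; back-projection is a pixel-driven weighted
  sparse matrix (angular step weighting, fan-beam `1/U^2` distance weight
  and cosine pre-weight, isocenter bin rescaling).
* **Autodiff.** Networks run on a small reverse-mode engine over float32
  numpy arrays (tape of closures, topological sort). Convolutions use a
  shift-and-slice tap loop (one BLAS matmul per kernel tap), group
  normalisation has a fused closed-form backward, and the projector enters
  the graph as a linear operator with its exact adjoint as gradient. All ops
  are finite-difference checked in the test suite.
* **Optimiser.** Adam (`beta1 = 0.9`, `beta2 = 0.999`, decoupled-style
  weight decay `1e-4`).

## 6. Default parameters

Study-scale defaults: 4 sinogram units / 4 U-Net levels / 4 enhancement
units at 32 channels, `T = 200` rounds of 100/100/200 iterations,
learning rates `2e-5` (client/shared) and `1e-4` (metamodel), `delta = 0.1`,
`alpha_k = 0.5`, `omega_c = 0.55`. These follow standard practice for
tens-of-thousands-of-iteration training runs.

The shipped **toy presets** (`situation1..3`) are sized for minutes on one
CPU core: 64×64 grids (3 mm voxels), 20 images per client, `T = 10` rounds
of 20 iterations, batch 1, 8 channels, 2 sinogram/enhancement units, and
learning rate `1e-3` (scaled up because the iteration count is ~100× lower).
Toy models enable the `filtered_backprojection` option so the domain bridge
is the full FBP operator: at 200 total iterations a 1×3-kernel sinogram
network cannot learn ramp filtering from scratch, and identity-initialised
networks then start exactly at FBP quality. The study-scale default keeps
the plain adjoint bridge.

* **situation1** — three paired low-mAs clients with heterogeneous
  geometries (including one fan-beam scanner).
* **situation2** — one low-mAs (`I0 = 2e5`), one limited-angle (2π/3), one
  sparse-view (96 of 192 views) client.
* **situation3** — one paired and two unpaired low-mAs clients.

## 7. Limitations

* Phantoms are piecewise-constant and 2-D; no scatter, beam hardening,
  detector crosstalk or motion are modelled, and the Poisson model is
  monoenergetic with an idealised count floor.
* Toy-scale training (200 iterations per client) demonstrates mechanism, not
  headline image quality; at this scale the mutual-learning and metamodel
  effects on the personalised client model are small compared with
  seed-to-seed variation, and the both-modules-off averaging baseline can tie or
  slightly exceed the full mode in mean PSNR, while the weight-divergence
  reduction from metadata-anchored aggregation is clearly visible.
* The sparse system matrix is precomputed per geometry, which is fast and
  exact for desk-scale grids but memory-bound for clinical-resolution
  volumes.
* The federation is simulated sequentially in one process; no communication
  latency, stragglers or client dropout are modelled.
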