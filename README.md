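# fcsfrap

Analysis of live-cell protein dynamics from fluorescence correlation
spectroscopy (FCS) and fluorescence recovery after photobleaching (FRAP),
built for proteins that partition between a freely diffusing cytosolic pool
and a membrane-bound pool — the situation of farnesylated peripheral
membrane proteins such as PRL-1, whose plasma-membrane accumulation is
sustained by fast exchange with the cytosol rather than by vesicular
traffic.

The package covers the full measurement chain:

* **Autocorrelation models.** The one-component free 3D diffusion ACF

  $$G(\tau) = \frac{1}{N}\left(1+\frac{\tau}{\tau_D}\right)^{-1}\left(1+\frac{\tau}{s^2\tau_D}\right)^{-1/2}$$

  and the two-component model combining a fast free 3D term (fraction
  $F_1$) with a slow free 2D membrane term,

  $$G(\tau) = \frac{1}{N}\left[\frac{F_1}{\left(1+\frac{\tau}{\tau_{d1}}\right)\sqrt{1+\frac{\tau}{s^2\tau_{d1}}}}+\frac{1-F_1}{1+\frac{\tau}{\tau_{d2}}}\right]$$

  where $N$ is the mean occupancy of the confocal volume, $s$ the
  axial-to-lateral structure parameter and $\tau_{d1} < \tau_{d2}$ the
  translational diffusion times. Diffusion coefficients follow from the
  calibrated lateral beam waist via $D = W_{xy}^2 / 4\tau_d$.
* **Calibration.** $W_{xy}$ and $s$ are obtained by fitting the ACF of a
  reference dye of known $D$ (Atto-488, 400 µm²/s); $s$ is then held fixed
  in all cell fits.
* **Multi-tau correlator.** Binned photon-count traces are correlated on a
  quasi-logarithmic lag grid with symmetric normalization, and replicate
  curves (e.g. ten 10 s runs per cell) are averaged before fitting.
* **Model selection.** One- versus two-component fits are compared by AIC,
  optionally backed by a runs test on the one-component residuals.
* **FRAP.** Raw bleached-ROI / whole-cell / background intensity vectors are
  bleach-corrected as $(I_b - B_g)/(I_c - B_g)$, normalized to the plateau,
  and fitted with the anomalous-diffusion recovery model
  $F(t) = \bigl(f_d + f_i (t/m)^\alpha\bigr)/\bigl(1 + (t/m)^\alpha\bigr)$,
  yielding the half-recovery time $t_{1/2} = m$ and the mobile fraction
  $(f_i - f_d)/(1 - f_d)$.
* **Image quantification.** Background-subtracted membrane/total intensity
  ratios over ROI masks and Pearson colocalization (plain or Costes
  auto-thresholded).
* **Synthetic data.** Every input can be generated with known ground truth,
  including a Brownian-dynamics simulator of diffusing emitters (3D
  cytosolic pool plus a 2D pool confined to a membrane plane) observed
  through a Gaussian confocal volume with Poisson photon statistics.

## Worked example

Generate a noiseless two-component curve at the parameters typical of a
membrane-proximal measurement and fit it:

```sh
$ fcsfrap simulate --kind acf --out-dir demo
wrote synthetic acf data to demo
$ fcsfrap fit-acf demo/acf.csv --wxy 0.145 --s 5.0 --out demo/report.json
acf: two_component_3d2d, D_fast = 38.7 um^2/s, D_slow = 1.30 um^2/s, slow fraction = 27.0%
```

Model selection picks the two-component model; the fast (cytosolic) pool
diffuses at 38.7 µm²/s, the slow (membrane) pool at 1.30 µm²/s, and 27% of
the correlation amplitude comes from the membrane component — the fitted
diffusion times converted through the 145 nm beam waist.

The same from Python, including calibration:

```python
import numpy as np
import fcsfrap as ff

lags = np.geomspace(1e-5, 0.1, 200)
dye, _ = ff.generate_analytic_acf(ff.ACFParams1C(1.0, 13.14e-6),
                                  ff.BeamGeometry(0.145, 5.0), lags)
report = ff.run_calibration(dye)          # wxy = 145.0 nm, s = 5.00
```

FRAP, from raw intensity vectors:

```sh
$ fcsfrap simulate --kind frap --out-dir demo
$ fcsfrap fit-frap demo/frap.csv
group fit over 1 cells: t_1/2 = 2.00 s, mobile fraction = 103.4%
```

The half-recovery time of 2 s is recovered exactly. Note that plateau
normalization rescales the plateau to ≈ 1 by construction, so the mobile
fraction of a plateau-normalized curve saturates near (or slightly above)
100%; mobile fractions meaningfully below 100% arise when the recovery
curve keeps its pre-bleach scale, as in `fit_frap` applied to an
unnormalized model curve (fd = 0.1, fi = 0.91 gives 90.0%).

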