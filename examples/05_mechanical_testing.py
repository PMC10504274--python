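"""Engineering stress-strain analysis of simulated cord compression tests.

Force-displacement records of ~3 mm cord samples compressed to 70% strain
are converted to engineering stress-strain curves; the Young's modulus is
the OLS slope over the 10-20% strain range.  Pairing each sample's modulus
with a strain ratio then exercises the one-parameter hyperbola fit
E = c / SR that expresses the expected inverse proportionality between
imaged strain and stiffness.
"""

import numpy as np

import cordelast as ce

rng = np.random.default_rng(3)
moduli, ratios = [], []
for i, e_true in enumerate([4.0, 6.0, 9.0, 14.0, 20.0, 30.0]):
    force, disp, area0, length0 = ce.generate_compression_record(
        e_true, noise_kpa=0.05, seed=i)
    curve = ce.engineering_curve(force, disp, area0, length0)
    est = ce.fit_modulus(curve)
    sr = 2.5 / e_true * (1 + rng.normal(0, 0.05))     # softer cord strains more
    moduli.append(est.e_kpa)
    ratios.append(sr)
    print(f"sample {i}: E_true {e_true:5.1f} kPa -> fitted {est.e_kpa:5.2f} kPa "
          f"(r2 {est.r2:.4f}), SR {sr:.3f}")

fit = ce.fit_hyperbola(ratios, moduli)
print(f"\nhyperbola fit E = c/SR: c = {fit.c_kpa:.3f} kPa "
      f"(generator used 2.5), residual SS = {fit.residual_ss:.3f}")
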