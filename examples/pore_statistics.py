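"""Fractal pore-size statistics of a skin layer.

Builds the pore network of a dermis-like layer (porosity 0.5), samples
capillary diameters by inverse-transform Monte Carlo, and compares the
empirical distribution with the analytic fractal size law.
"""

import numpy as np
from scipy import stats

from skinetc import PoreNetworkSpec, sample_pore_diameters, rev_geometry
from skinetc.fractal import pore_cdf, pore_cdf_max

spec = PoreNetworkSpec.from_porosity(
    porosity=0.5, lambda_min=5e-6, lambda_max=5e-4, tortuosity_dim=1.05
)
geo = rev_geometry(spec)
print(f"fractal dimension Df        : {spec.fractal_dim:.4f}")
print(f"fractal criterion (ratio^Df): {spec.criterion:.2e}  (≈0 required)")
print(f"total pore area Ac          : {geo.pore_area:.3e} m^2")
print(f"REV side length L0          : {geo.side_length:.3e} m")

lam = sample_pore_diameters(10_000, spec, seed=42)
ks = stats.kstest(lam, lambda x: pore_cdf(x, spec) / pore_cdf_max(spec))
print(f"\nsampled {lam.size} diameters in [{lam.min():.2e}, {lam.max():.2e}] m")
print(f"median diameter             : {np.median(lam):.3e} m")
print(f"KS distance to analytic cdf : {ks.statistic:.4f}  (< 0.02 expected)")
# Most pores are near lambda_min (the distribution is heavy at small sizes),
# but the rare wide capillaries dominate flow and heat transport.
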