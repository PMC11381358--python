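"""Filter-binding analysis: fraction bound and hyperbolic K_d fits.

In a membrane-sandwich filter binding assay, protein-bound RNA is retained
on the nitrocellulose membrane and free RNA passes through to the nylon
membrane, so for each reaction

    fraction_bound = I_nitro / (I_nitro + I_nylon).

Across a protein concentration series the fractions follow the
single-site equilibrium hyperbola

    f(c) = f_max * c / (c + K_d),

fit here by nonlinear least squares with multiple starting values of K_d
(min, geometric mean, max of the concentrations). Concentrations are in nM
throughout; f_max is free within (0, 1.2] to tolerate normalization noise.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

F_MAX_CAP = 1.2


@dataclasses.dataclass
class BindingFit:
    kd: float
    f_max: float
    rss: float
    n_points: int


def fraction_bound(nitro: float, nylon: float) -> float:
    if nitro < 0 or nylon < 0:
        raise ValueError("intensities must be >= 0")
    total = nitro + nylon
    if total == 0:
        raise ValueError("undefined observation: both membrane intensities are zero")
    return nitro / total


def hyperbola(c, f_max, kd):
    return f_max * c / (c + kd)


def fit_binding(observations: pd.DataFrame) -> BindingFit:
    """Fit f(c) = f_max*c/(c+kd) to a concentration series.

    ``observations`` needs columns protein_conc_nM and fraction_bound, or
    intensity_nitro/intensity_nylon from which fractions are computed.
    Raises on fewer than 3 distinct concentrations or if no start converges
    to a finite optimum (e.g. a flat, curvature-free series).
    """
    obs = observations.copy()
    if "fraction_bound" not in obs.columns:
        obs["fraction_bound"] = [
            fraction_bound(n, y) for n, y in zip(obs.intensity_nitro, obs.intensity_nylon)
        ]
    c = obs.protein_conc_nM.to_numpy(dtype=float)
    f = obs.fraction_bound.to_numpy(dtype=float)
    if np.unique(c).size < 3:
        raise ValueError("need >= 3 distinct concentrations to fit")

    gmean = float(np.exp(np.mean(np.log(c[c > 0])))) if np.any(c > 0) else 1.0
    starts = [float(c[c > 0].min()), gmean, float(c.max())]
    f0 = max(float(f.max()), 1e-3)

    best: BindingFit | None = None
    diagnostics = []
    for kd0 in starts:
        try:
            popt, _ = curve_fit(
                hyperbola, c, f, p0=[min(f0, F_MAX_CAP), kd0],
                bounds=([1e-9, 1e-9], [F_MAX_CAP, np.inf]), maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            diagnostics.append(f"start kd={kd0:g}: {exc}")
            continue
        resid = f - hyperbola(c, *popt)
        rss = float(resid @ resid)
        if best is None or rss < best.rss:
            best = BindingFit(kd=float(popt[1]), f_max=float(popt[0]), rss=rss, n_points=c.size)
    if best is None:
        raise RuntimeError("binding fit failed from all starts: " + "; ".join(diagnostics))
    if np.allclose(f, f.mean()):
        raise RuntimeError("degenerate series: fraction bound shows no curvature")
    return best
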