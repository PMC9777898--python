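"""Normal-theory oracles for the synthetic cohort's latent risk model.

The generator decomposes the latent severity score as

    s = sqrt(w_img) * z_img + sqrt(w_tab) * z_tab + sqrt(1 - w_img - w_tab) * z_res

with independent standard-normal factors, and sets the severe label to
``s > tau``.  Because the label thresholds the *sum*, ranking subjects by
``s`` itself separates the classes perfectly (fused Bayes AUC = 1 in the
noiseless limit), while ranking by a single factor has an AUC given by a
two-dimensional Gaussian integral with no elementary closed form.  This
module evaluates that integral by deterministic Gauss-Legendre quadrature,
so tests can compare trained models against exact values that were never
produced by the models themselves.

For the unconditional two-class Gaussian location-shift model (class means
separated by ``d``, unit variances) the classical closed form
``AUC = Phi(d / sqrt(2))`` applies and is provided for cross-checking the
quadrature machinery.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

__all__ = [
    "severity_threshold",
    "gaussian_shift_auc",
    "unimodal_severity_auc",
    "fused_severity_auc",
]

#: Fraction of subjects in the severe group the generator is calibrated to.
SEVERE_FRACTION = 0.458


def severity_threshold(severe_fraction: float = SEVERE_FRACTION) -> float:
    """Latent cutoff tau with P(s > tau) = severe_fraction for s ~ N(0,1)."""
    return float(norm.ppf(1.0 - severe_fraction))


def gaussian_shift_auc(d: float) -> float:
    """AUC of the equal-variance two-Gaussian model with mean shift ``d``."""
    return float(norm.cdf(d / np.sqrt(2.0)))


def unimodal_severity_auc(
    weight: float,
    severe_fraction: float = SEVERE_FRACTION,
    n_nodes: int = 400,
) -> float:
    """Bayes AUC for ranking the severe label by one latent factor alone.

    The factor is ``a * z`` with ``a = sqrt(weight)``; the label is
    ``1{a*z + r > tau}`` with residual ``r ~ N(0, 1 - weight)`` independent
    of ``z``.  Evaluates

        P(z1 > z2 | label1 = 1, label2 = 0)

    by Gauss-Legendre quadrature over the two independent factors.
    """
    if not 0.0 < weight <= 1.0:
        raise ValueError(f"weight must be in (0, 1], got {weight}")
    tau = severity_threshold(severe_fraction)
    a = np.sqrt(weight)
    sr = np.sqrt(max(1.0 - weight, 0.0))

    # integrate over z in [-8, 8] with GL nodes
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    z = 8.0 * x
    wz = 8.0 * w * norm.pdf(z)
    if sr == 0.0:
        p_pos = (a * z > tau).astype(float)  # degenerate residual
    else:
        p_pos = norm.sf((tau - a * z) / sr)
    p_neg = 1.0 - p_pos

    # P(z1 > z2, y1=1, y2=0); half-credit at ties has measure zero here
    gt = (z[:, None] > z[None, :]).astype(float)
    num = float(wz @ (gt * p_pos[:, None] * p_neg[None, :]) @ wz)
    denom = float((wz @ p_pos) * (wz @ p_neg))
    return num / denom


def fused_severity_auc(noise_sd: float = 0.0) -> float:
    """Bayes AUC for ranking the severe label by the full latent score.

    With a noiseless observation of ``s`` the label is a deterministic
    threshold of the ranking score, so the AUC is exactly 1.  Additive
    observation noise is not modelled here; callers wanting that case
    should use :func:`unimodal_severity_auc` with an effective weight.
    """
    if noise_sd != 0.0:
        raise NotImplementedError("only the noiseless fused case is closed-form")
    return 1.0
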