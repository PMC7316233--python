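"""Label transformation chain: empirical logit followed by the inverse
hyperbolic sine, and the continuous inverse used to map predictions back to
proportional mortality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from resistmap.datamodel import BioassayObservation, VgscObservation

#: Default half-count smoothing constant for the empirical logit.
DEFAULT_SMOOTHING = 0.5

#: Default reference trial count for back-transforming map surfaces.
DEFAULT_N_REF = 100


@dataclass(frozen=True)
class TransformedLabel:
    """A label on the modelling scale (empirical logit then IHS)."""

    value: float
    source_kind: str  # "bioassay" | "allele"


def empirical_logit(successes, trials, c: float = DEFAULT_SMOOTHING):
    """Empirical logit log((k + c) / (n - k + c)).

    Finite at k = 0 and k = n, strictly increasing in k, and antisymmetric:
    f(k, n, c) = -f(n - k, n, c).
    """
    k = np.asarray(successes, dtype=float)
    n = np.asarray(trials, dtype=float)
    if c <= 0:
        raise ValueError("smoothing constant c must be > 0")
    if np.any(n < 1):
        raise ValueError("trials must be >= 1")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("successes must satisfy 0 <= successes <= trials")
    out = np.log((k + c) / (n - k + c))
    return float(out) if out.ndim == 0 else out


def ihs(x):
    """Inverse hyperbolic sine log(x + sqrt(x^2 + 1)); odd, strictly increasing."""
    return np.arcsinh(x)


def transform(obs: BioassayObservation | VgscObservation, c: float = DEFAULT_SMOOTHING) -> TransformedLabel:
    """Transform an observation's proportion to the modelling scale.

    The stored proportion is converted back to an integer success count by
    rounding before the half-count-corrected logit; the IHS is applied second.
    """
    if isinstance(obs, BioassayObservation):
        p, n, kind = obs.mortality, obs.n_tested, "bioassay"
    else:
        p, n, kind = obs.frequency, obs.n_alleles, "allele"
    k = int(round(p * n))
    return TransformedLabel(value=float(ihs(empirical_logit(k, n, c))), source_kind=kind)


def transform_proportion(p, n, c: float = DEFAULT_SMOOTHING):
    """Vectorised transform of proportions with per-row denominators."""
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    k = np.round(p * n)
    return ihs(empirical_logit(k, n, c))


def inverse_transform(value, c: float = DEFAULT_SMOOTHING, n_ref: int = DEFAULT_N_REF):
    """Map a transformed value back to a proportion in [0, 1].

    Inverts the IHS (sinh), then the empirical logit under a continuous
    relaxation with a fixed reference trial count ``n_ref``: solving
    z = log((p*n_ref + c) / ((1 - p)*n_ref + c)) for p gives
    p = (E*n_ref + c*(E - 1)) / (n_ref*(1 + E)) with E = exp(z).  The result
    is clamped to [0, 1].
    """
    z = np.sinh(np.asarray(value, dtype=float))
    # Piecewise form avoids exp overflow at large |z|.
    neg = np.exp(np.minimum(z, 0.0))  # e^z for z <= 0
    pos = np.exp(np.minimum(-z, 0.0))  # e^-z for z > 0
    p = np.where(
        z <= 0,
        (neg * n_ref + c * (neg - 1.0)) / (n_ref * (1.0 + neg)),
        (n_ref + c * (1.0 - pos)) / (n_ref * (pos + 1.0)),
    )
    p = np.clip(p, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p
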