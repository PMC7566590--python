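"""Predicted-flow computation: gravity and radiation model families.

Both families are *production constrained*: each site carries an
outflow parameter ``t_i`` and the predicted flows out of site *i*
(approximately) sum to ``t_i``.

Gravity (power or exponential deterrence ``f``)::

    Fhat_ij = t_i * n_j * f(d_ij) / sum_{k != i} n_k * f(d_ik)

which satisfies the production constraint exactly.  The denominator
excludes ``k = i``: the sum is over possible destinations, and with a
power-law deterrence the ``d_ii = 0`` term would be singular.

Radiation::

    Fhat_ij = t_i * m_i * n_j / ((m_i + s_ij) * (m_i + n_j + s_ij))

where ``s_ij`` is the intervening-opportunities measure — the total
attractiveness of sites *strictly* closer to *i* than *j*, excluding
*i* and *j* themselves — and ``m_i`` is an "aspiration" parameter
controlling how far commuters from *i* travel.  The row sums fall short
of ``t_i`` by a factor ``(N_c - m_i)/N_c`` (``N_c = sum_k n_k``); the
*normalised* variant multiplies by ``N_c/(N_c - m_i)`` so the
production constraint holds exactly.

Eight conventional mappings of site data values (population ``P``,
departures ``O``, arrivals ``I``) onto the radiation parameters
``(m, n, t)`` are provided by :func:`make_variant`, labelled A–H:

====== ===== ===== ========= ==========
variant  m_i   n_i   t_i      normalised
====== ===== ===== ========= ==========
A        P     P     P          no
B        O     O     O          no
C        O     O     O          yes
D        O     I     O          no
E        I     I     O          yes
F        P     P     alpha*P    no
G        O     O     alpha*O    no
H        I     I     alpha*O    yes
====== ===== ===== ========= ==========

Variants F, G, H carry a single fitted global factor ``alpha``; the
others are parameter free.  Variant A is the original radiation model
up to the fitted factor of variant F.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import DistanceMatrix, SiteTable
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

RADIATION_VARIANTS = "ABCDEFGH"
#: variants whose t_i carries the fitted global factor alpha
FITTED_VARIANTS = "FGH"
#: (m, n, t) source columns and normalisation flag per Table-style mapping
_VARIANT_TABLE: dict[str, tuple[str, str, str, bool]] = {
    "A": ("population", "population", "population", False),
    "B": ("out_flow", "out_flow", "out_flow", False),
    "C": ("out_flow", "out_flow", "out_flow", True),
    "D": ("out_flow", "in_flow", "out_flow", False),
    "E": ("in_flow", "in_flow", "out_flow", True),
    "F": ("population", "population", "population", False),
    "G": ("out_flow", "out_flow", "out_flow", False),
    "H": ("in_flow", "in_flow", "out_flow", True),
}


@dataclass
class ModelSpec:
    """A fully specified model: family, variant and per-site parameters.

    Exactly the parameters the variant demands are set: gravity uses
    ``t``, ``n``, ``deterrence`` and ``beta``; radiation uses ``t``,
    ``n``, ``m``, ``normalised`` and (variants F–H) ``alpha``.
    """

    family: str  # "gravity" | "radiation"
    t: np.ndarray
    n: np.ndarray
    m: np.ndarray | None = None
    variant: str | None = None  # A..H for radiation, deterrence name for gravity
    deterrence: str | None = None  # "power" | "exponential"
    beta: float | None = None
    alpha: float | None = None
    normalised: bool = False
    source_columns: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("gravity", "radiation"):
            raise ValidationError(f"unknown model family {self.family!r}")
        self.t = np.asarray(self.t, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.m is not None:
            self.m = np.asarray(self.m, dtype=float)
        for name in ("t", "n", "m"):
            arr = getattr(self, name)
            if arr is not None and np.any(arr < 0):
                raise ValidationError(f"site parameter {name} must be nonnegative")
        if self.family == "gravity":
            if self.deterrence not in ("power", "exponential"):
                raise ValidationError("gravity requires deterrence 'power' or 'exponential'")
            if self.beta is None or self.beta < 0:
                raise ValidationError("gravity requires beta >= 0")
        else:
            if self.m is None:
                raise ValidationError("radiation requires the aspiration array m")

    @property
    def k_fitted(self) -> int:
        """Number of fitted global parameters (0 or 1)."""
        if self.family == "gravity":
            return 1
        return 1 if self.variant in FITTED_VARIANTS else 0

    def predict(self, D: DistanceMatrix) -> np.ndarray:
        """Predicted flow matrix ``Fhat`` for this spec."""
        if self.family == "gravity":
            return gravity_predict(self.t, self.n, D, self.beta, self.deterrence)
        s = intervening_opportunities(self.n, D)
        return radiation_predict(self.t, self.m, self.n, s, self.normalised)

    def to_config(self) -> dict:
        """JSON/YAML-safe description enabling exact re-runs."""
        cfg = {
            "family": self.family,
            "variant": self.variant,
            "deterrence": self.deterrence,
            "beta": self.beta,
            "alpha": self.alpha,
            "normalised": self.normalised,
            "source_columns": dict(self.source_columns),
        }
        return {k: v for k, v in cfg.items() if v is not None}


@dataclass
class InterveningOpportunities:
    """The ``s_ij`` matrix and the total opportunity count ``N_c``."""

    s: np.ndarray
    N_c: float


def deterrence_matrix(D: DistanceMatrix, beta: float, deterrence: str) -> np.ndarray:
    """Elementwise ``f(d_ij)`` with an unusable diagonal set to zero."""
    d = D.values
    if deterrence == "power":
        if beta > 0:
            D.require_positive_offdiagonal()
        with np.errstate(divide="ignore"):
            f = np.where(d > 0, d, 1.0) ** (-beta)
    elif deterrence == "exponential":
        f = np.exp(-beta * d)
    else:
        raise ValidationError(f"unknown deterrence {deterrence!r}")
    np.fill_diagonal(f, 0.0)
    return f


def gravity_predict(
    t: np.ndarray,
    n: np.ndarray,
    D: DistanceMatrix,
    beta: float,
    deterrence: str = "power",
) -> np.ndarray:
    """Production-constrained gravity predictions.

    Each row *i* distributes ``t_i`` over destinations ``j != i`` with
    weight ``n_j f(d_ij)``, so row sums equal ``t_i`` exactly.
    """
    t = np.asarray(t, dtype=float)
    n = np.asarray(n, dtype=float)
    w = n[None, :] * deterrence_matrix(D, beta, deterrence)
    denom = w.sum(axis=1)
    if np.any(denom <= 0):
        raise ValidationError(
            "gravity denominator vanished for some origin: either the "
            "attractiveness is zero at every other site, or the deterrence "
            "underflowed (check that beta matches the distance units)"
        )
    fhat = t[:, None] * w / denom[:, None]
    np.fill_diagonal(fhat, 0.0)
    return fhat


def intervening_opportunities(
    n: np.ndarray, D: DistanceMatrix, warn_on_ties: bool = True
) -> InterveningOpportunities:
    """Compute ``s_ij``: opportunities strictly closer to *i* than *j*.

    ``s_ij = sum_{k != i, d_ik < d_ij} n_k``.  The strict inequality
    (theta(0) = 0) excludes ``k = j`` automatically and excludes any
    site tied in distance with *j*.  Exact distance ties between
    distinct destinations of the same origin break the telescoping
    row-sum identity of the radiation model, so they trigger a warning.
    """
    n = np.asarray(n, dtype=float)
    d = D.values
    nsites = d.shape[0]
    s = np.empty((nsites, nsites))
    tie_rows = 0
    for i in range(nsites):
        others = np.delete(np.arange(nsites), i)
        di = d[i, others]
        order = np.argsort(di, kind="stable")
        di_sorted = di[order]
        if warn_on_ties and np.any(np.diff(di_sorted) == 0):
            tie_rows += 1
        csum = np.concatenate(([0.0], np.cumsum(n[others][order])))
        # number of strictly closer sites for every destination distance
        pos = np.searchsorted(di_sorted, d[i], side="left")
        s[i] = csum[pos]
    np.fill_diagonal(s, 0.0)
    if tie_rows:
        msg = (
            f"exact distance ties found in {tie_rows} origin row(s); tied sites "
            "are excluded from each other's intervening opportunities and the "
            "radiation row-sum identity will not hold exactly"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return InterveningOpportunities(s=s, N_c=float(n.sum()))


def jitter_distances(D: DistanceMatrix, seed: int, magnitude: float = 1e-9) -> DistanceMatrix:
    """Deterministically perturb distances to break exact ties.

    Adds a seeded uniform jitter of the given magnitude (km) to each
    unordered pair.  Off by default everywhere; offered for systems on
    regular lattices where ties are structural.
    """
    rng = np.random.default_rng(seed)
    d = D.values.copy()
    i, j = np.triu_indices(d.shape[0], k=1)
    eps = rng.uniform(0.0, magnitude, size=i.size)
    d[i, j] += eps
    d[j, i] = d[i, j]
    return DistanceMatrix(d)


def normalisation_factors(m: np.ndarray, N_c: float) -> np.ndarray:
    """Per-origin factors ``N_c / (N_c - m_i)`` (>= 1).

    These restore the production constraint in the radiation model;
    when ``N_c >> m_i`` the correction is close to 1.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m >= N_c):
        raise ValidationError("normalisation undefined: m_i >= N_c for some site")
    return N_c / (N_c - m)


def radiation_predict(
    t: np.ndarray,
    m: np.ndarray,
    n: np.ndarray,
    s: InterveningOpportunities,
    normalised: bool = False,
) -> np.ndarray:
    """Radiation-model predictions, optionally normalised.

    A site with ``m_i = 0`` has no defined outflow distribution; this
    is an error unless ``t_i = 0`` too (in which case its row is zero).
    """
    t = np.asarray(t, dtype=float)
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((m == 0) & (t > 0)):
        raise ValidationError(
            "inconsistent parameters: m_i = 0 with t_i > 0 leaves the outflow "
            "distribution undefined"
        )
    denom = (m[:, None] + s.s) * (m[:, None] + n[None, :] + s.s)
    with np.errstate(invalid="ignore", divide="ignore"):
        fhat = t[:, None] * m[:, None] * n[None, :] / denom
    fhat = np.where(denom > 0, fhat, 0.0)
    if normalised:
        fhat = normalisation_factors(m, s.N_c)[:, None] * fhat
    np.fill_diagonal(fhat, 0.0)
    return fhat


def make_variant(
    sites: SiteTable, variant: str, alpha: float | None = None
) -> ModelSpec:
    """Build the radiation :class:`ModelSpec` for variant A–H.

    ``alpha`` must be supplied exactly when the variant is F, G or H
    (where ``t_i`` is ``alpha`` times the mapped column).
    """
    variant = variant.upper()
    if variant not in _VARIANT_TABLE:
        raise ValidationError(f"unknown radiation variant {variant!r}")
    fitted = variant in FITTED_VARIANTS
    if fitted and alpha is None:
        raise ValidationError(f"variant {variant} requires the global factor alpha")
    if not fitted and alpha is not None:
        raise ValidationError(f"variant {variant} takes no global factor alpha")
    if fitted and alpha <= 0:
        raise ValidationError("alpha must be positive")
    m_col, n_col, t_col, normalised = _VARIANT_TABLE[variant]
    t = np.asarray(getattr(sites, t_col), dtype=float)
    if fitted:
        t = alpha * t
    return ModelSpec(
        family="radiation",
        variant=variant,
        t=t,
        n=np.asarray(getattr(sites, n_col), dtype=float),
        m=np.asarray(getattr(sites, m_col), dtype=float),
        alpha=alpha if fitted else None,
        normalised=normalised,
        source_columns={"m": m_col, "n": n_col, "t": t_col},
    )


def make_gravity(
    sites: SiteTable, beta: float, deterrence: str = "power"
) -> ModelSpec:
    """Gravity spec with the conventional data mapping ``t=O``, ``n=I``."""
    return ModelSpec(
        family="gravity",
        variant=deterrence,
        t=np.asarray(sites.out_flow, dtype=float),
        n=np.asarray(sites.in_flow, dtype=float),
        deterrence=deterrence,
        beta=beta,
        source_columns={"t": "out_flow", "n": "in_flow"},
    )
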