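"""Seeded synthetic origin-destination systems for testing and recovery.

Real commuting data have three statistical signatures the generator
reproduces: heavy-tailed site populations (county populations span four
orders of magnitude), a flow-size distribution dominated by zeros and
small counts, and in/out-flow asymmetry at individual sites (a
commercial centre can attract twice as many commuters as it sends out).

The pipeline is:

1. scatter ``n_sites`` uniformly in a lat/lon box and draw populations
   ``P_i`` from a lognormal (rounded up to >= 1);
2. form ground-truth predictions from a chosen model (by default a
   production-constrained gravity model with power deterrence) with
   ``t_i = outflow_fraction * P_i`` and attractiveness ``n_i = P_i``;
3. draw each observed flow ``F_ij`` as an independent Poisson count
   with mean ``Fhat_ij``;
4. write the *realised* marginals ``O_i``, ``I_i`` (row/column sums of
   the sampled flows) back into the site table, so that model fitting
   sees data values, exactly as with real data, never latent truths.

Everything is driven by a single mandatory seed; per-stage substreams
are spawned deterministically, so each artefact is byte-identical
across runs with an equal config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .data_model import (
    DistanceMatrix,
    FlowMatrix,
    SiteTable,
    derive_marginals,
    haversine_distances,
)
from .exceptions import ValidationError
from .models import ModelSpec, make_gravity, make_variant

#: continental-US-like default box (degrees): spans ~1500 km N-S, ~3000 km E-W
DEFAULT_LAT_RANGE = (33.0, 47.0)
DEFAULT_LON_RANGE = (-117.0, -81.0)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study system.

    Defaults emulate a scaled-down county-level commuting system:
    lognormal populations with median ~22,000 and a heavy right tail
    (``sigma = 1.4`` on the log scale), about a third of each
    population commuting out, and distance deterrence ``beta = 2``.
    """

    n_sites: int = 200
    seed: int | None = None
    lat_range: tuple[float, float] = DEFAULT_LAT_RANGE
    lon_range: tuple[float, float] = DEFAULT_LON_RANGE
    pop_lognormal_mu: float = 10.0
    pop_lognormal_sigma: float = 1.4
    outflow_fraction: float = 0.35
    truth_family: str = "gravity"
    truth_variant: str | None = None  # radiation variant letter, if radiation
    truth_deterrence: str = "power"
    truth_beta: float = 2.0
    truth_alpha: float | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory: no implicit randomness")
        if self.n_sites < 2:
            raise ValidationError("need at least two sites")
        for lo, hi, name in (
            (*self.lat_range, "lat_range"),
            (*self.lon_range, "lon_range"),
        ):
            if not (np.isfinite(lo) and np.isfinite(hi)) or hi <= lo:
                raise ValidationError(f"degenerate {name}: ({lo}, {hi})")
        if not (0 < self.outflow_fraction <= 1):
            raise ValidationError("outflow_fraction must be in (0, 1]")
        if self.pop_lognormal_sigma < 0:
            raise ValidationError("pop_lognormal_sigma must be >= 0")
        if self.truth_family not in ("gravity", "radiation"):
            raise ValidationError(f"unknown truth family {self.truth_family!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("lat_range", "lon_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "seed": self.seed,
            "lat_range": list(self.lat_range),
            "lon_range": list(self.lon_range),
            "pop_lognormal_mu": self.pop_lognormal_mu,
            "pop_lognormal_sigma": self.pop_lognormal_sigma,
            "outflow_fraction": self.outflow_fraction,
            "truth_family": self.truth_family,
            "truth_variant": self.truth_variant,
            "truth_deterrence": self.truth_deterrence,
            "truth_beta": self.truth_beta,
            "truth_alpha": self.truth_alpha,
        }


@dataclass
class SyntheticSystem:
    """Everything :func:`generate_system` produces, plus ground truth."""

    sites: SiteTable
    distances: DistanceMatrix
    flows: FlowMatrix
    truth: ModelSpec
    config: SyntheticConfig
    predicted: np.ndarray = field(repr=False, default=None)


def _substreams(seed: int, count: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(count)]


def generate_sites(config: SyntheticConfig) -> tuple[SiteTable, DistanceMatrix]:
    """Scatter sites and draw heavy-tailed populations.

    Marginals ``O_i``, ``I_i`` are initialised to zero; they become
    meaningful once flows have been sampled (:func:`generate_system`).
    """
    rng = _substreams(config.seed, 2)[0]
    n = config.n_sites
    lat = rng.uniform(*config.lat_range, size=n)
    lon = rng.uniform(*config.lon_range, size=n)
    pop = np.ceil(
        rng.lognormal(config.pop_lognormal_mu, config.pop_lognormal_sigma, size=n)
    ).astype(np.int64)
    pop = np.maximum(pop, 1)
    sites = SiteTable(
        site_id=np.array([f"s{i:04d}" for i in range(n)], dtype=object),
        population=pop,
        out_flow=np.zeros(n, dtype=np.int64),
        in_flow=np.zeros(n, dtype=np.int64),
        lat=lat,
        lon=lon,
    )
    return sites, haversine_distances(sites)


def truth_model(config: SyntheticConfig, sites: SiteTable) -> ModelSpec:
    """Ground-truth spec with ``t = outflow_fraction * P``, ``n = P``.

    Attractiveness proportional to population is the generative
    convention; the *expected* inflow it induces is a geography-smoothed
    transform of ``P``, so the realised in-flow column handed to fitting
    resembles real data rather than echoing the truth parameter —
    parameter-recovery studies therefore refit the truth family with
    its own per-site inputs (see
    :func:`odmodels.inference.refit_global_parameter`).
    """
    t = config.outflow_fraction * sites.population.astype(float)
    if config.truth_family == "gravity":
        spec = make_gravity(sites, beta=config.truth_beta,
                            deterrence=config.truth_deterrence)
        spec.t = t
        spec.n = sites.population.astype(float)
        spec.source_columns = {"t": "outflow_fraction*population",
                               "n": "population"}
        return spec
    # Radiation truths that map to O/I columns cannot bootstrap from the
    # zero marginals of a freshly generated site table; they take
    # provisional marginals O = I = round(outflow_fraction * P) as their
    # inputs, and the realised marginals are written back after sampling.
    variant = (config.truth_variant or "A").upper()
    alpha = config.truth_alpha if variant in "FGH" else None
    proxy = np.maximum(np.round(t), 1).astype(np.int64)
    proto = sites.with_marginals(proxy, proxy)
    return make_variant(proto, variant, alpha=alpha)


def sample_flows(Fhat: np.ndarray, seed: int) -> FlowMatrix:
    """Independent Poisson draws with mean ``Fhat_ij`` per ordered pair."""
    fhat = np.asarray(Fhat, dtype=float)
    if not np.all(np.isfinite(fhat)) or np.any(fhat < 0):
        raise ValidationError("predicted means must be finite and nonnegative")
    rng = np.random.default_rng(seed)
    flows = rng.poisson(fhat)
    np.fill_diagonal(flows, 0)
    return FlowMatrix(flows.astype(np.int64))


def generate_system(config: SyntheticConfig) -> SyntheticSystem:
    """Full pipeline: sites -> truth predictions -> Poisson flows.

    The returned :class:`SiteTable` carries the realised marginals, so
    radiation variants B-H and the gravity fit all draw on observable
    data values, self-consistent with the sampled flow matrix.
    """
    sites, D = generate_sites(config)
    truth = truth_model(config, sites)
    fhat = truth.predict(D)
    flow_seed = int(np.random.SeedSequence(config.seed).spawn(2)[1].generate_state(1)[0] % (2**31))
    flows = sample_flows(fhat, flow_seed)
    out_flow, in_flow = derive_marginals(flows)
    sites = sites.with_marginals(out_flow, in_flow)
    return SyntheticSystem(
        sites=sites, distances=D, flows=flows, truth=truth,
        config=config, predicted=fhat,
    )
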