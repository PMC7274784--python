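"""Synthetic cytometry cohorts with known ground truth.

Events are drawn from a mixture of subpopulations directly in
arcsinh-transformed space: each population is a correlated Gaussian with a
per-marker location and scale, truncated below at a floor (default -0.5) to
mimic the small negative intensities that survive compensation.  Gaussians
in transformed space (rather than lognormal raw intensities) keep the ground
truth analytically tractable: the positive fraction of any marker under any
cutoff above the floor is a simple normal tail probability, which the tests
exploit.

The ``lupus_like`` preset emulates a gated CD4+CD44+ memory T-cell pool
from an autoimmune-prone mouse: a non-producing bulk, a PD-1-hi
IL-10-enriched subset, a PD-1-hi CXCR5+ follicular-helper-like subset, a
PD-1-hi Th1-like subset, and a planted PD-1-low IFN-g-hi subset with
elevated IL-21, TNF-a and IL-2 but no CXCR5 — the "super-functional"
polyfunctional phenotype.  Positive and negative modes of every marker are
separated by well over three pooled scales, so positivity cutoffs placed
between the modes are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .binning import CutoffSet
from .errors import ConfigError
from .events import EventTable

__all__ = [
    "PopulationSpec",
    "CohortSpec",
    "generate_events",
    "lupus_like_preset",
    "lupus_like_cutoffs",
    "lupus_planted_region",
    "expected_positive_fraction",
    "cohort_to_yaml",
    "cohort_from_yaml",
    "LUPUS_MARKERS",
]

LUPUS_MARKERS = ("PD-1", "IFN-g", "IL-21", "TNF-a", "IL-2", "IL-10", "CXCR5")

# baseline (autofluorescence-level) mode shared by all non-producing markers
_BASELINE_LOC = 0.2
_BASELINE_SCALE = 0.25


@dataclass(frozen=True)
class PopulationSpec:
    """One synthetic subpopulation.

    Markers absent from ``locations``/``scales`` fall back to the cohort's
    baseline (non-producing) mode.  ``correlation`` is a symmetric PSD
    matrix over the cohort's full ordered marker list (identity when None).
    """

    name: str
    fraction: float
    locations: dict[str, float] = field(default_factory=dict)
    scales: dict[str, float] = field(default_factory=dict)
    correlation: tuple | None = None

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ConfigError(
                f"population {self.name!r}: fraction must be in (0, 1], "
                f"got {self.fraction}"
            )
        for m, s in self.scales.items():
            if s < 0:
                raise ConfigError(
                    f"population {self.name!r}: scale for {m!r} must be >= 0"
                )
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            if c.ndim != 2 or c.shape[0] != c.shape[1]:
                raise ConfigError(
                    f"population {self.name!r}: correlation must be square"
                )
            if not np.allclose(c, c.T):
                raise ConfigError(
                    f"population {self.name!r}: correlation must be symmetric"
                )
            if np.linalg.eigvalsh(c).min() < -1e-8:
                raise ConfigError(
                    f"population {self.name!r}: correlation must be PSD"
                )
            object.__setattr__(
                self, "correlation", tuple(tuple(row) for row in c.tolist())
            )

    def location(self, marker: str) -> float:
        return float(self.locations.get(marker, _BASELINE_LOC))

    def scale(self, marker: str) -> float:
        return float(self.scales.get(marker, _BASELINE_SCALE))


@dataclass(frozen=True)
class CohortSpec:
    """A full synthetic cohort: mixture, size, noise, truncation and seed."""

    n_events: int
    markers: tuple[str, ...]
    populations: tuple[PopulationSpec, ...]
    noise_scale: float = 0.0
    floor: float = -0.5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        object.__setattr__(self, "populations", tuple(self.populations))
        if self.n_events < 1:
            raise ConfigError(f"n_events must be >= 1, got {self.n_events}")
        if not self.populations:
            raise ConfigError("cohort needs at least one population")
        if self.noise_scale < 0:
            raise ConfigError("noise_scale must be >= 0")
        total = sum(p.fraction for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"population fractions must sum to 1 (got {total:.12g})"
            )
        for p in self.populations:
            if p.correlation is not None and len(p.correlation) != len(self.markers):
                raise ConfigError(
                    f"population {p.name!r}: correlation is "
                    f"{len(p.correlation)}x{len(p.correlation)} but the cohort "
                    f"has {len(self.markers)} markers"
                )


def _allocate_counts(spec: CohortSpec) -> list[int]:
    """Rounded fraction x n_events per population; remainder to the largest."""
    counts = [int(round(p.fraction * spec.n_events)) for p in spec.populations]
    remainder = spec.n_events - sum(counts)
    if remainder != 0:
        largest = int(np.argmax([p.fraction for p in spec.populations]))
        counts[largest] += remainder
    if min(counts) < 0:
        raise ConfigError("rounding produced a negative population count")
    return counts


def generate_events(spec: CohortSpec) -> EventTable:
    """Draw a cohort; ground-truth population labels land in meta['population'].

    Events are drawn population by population in spec order, fully
    reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _allocate_counts(spec)
    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    d = len(spec.markers)
    for pop, count in zip(spec.populations, counts):
        mean = np.array([pop.location(m) for m in spec.markers])
        sd = np.array([pop.scale(m) for m in spec.markers])
        corr = (
            np.asarray(pop.correlation, dtype=float)
            if pop.correlation is not None
            else np.eye(d)
        )
        cov = np.outer(sd, sd) * corr
        if count == 0:
            continue
        if np.allclose(cov, 0):
            block = np.tile(mean, (count, 1))
        else:
            block = rng.multivariate_normal(mean, cov, size=count, method="svd")
        if spec.noise_scale > 0:
            block = block + rng.normal(0.0, spec.noise_scale, size=block.shape)
        blocks.append(np.maximum(block, spec.floor))
        labels.append(np.repeat(pop.name, count))
    values = np.vstack(blocks) if blocks else np.empty((0, d))
    return EventTable(
        pd.DataFrame(values, columns=list(spec.markers)),
        sample_id=f"synthetic-seed{spec.seed}",
        meta={
            "population": np.concatenate(labels) if labels else np.array([]),
            "cohort_seed": spec.seed,
        },
    )


# ---------------------------------------------------------------------------
# lupus-like preset

_POSITIVE_MODES = {
    # marker: (positive-mode location, scale)
    "PD-1_low": (1.6, 0.30),
    "PD-1_hi": (3.2, 0.30),
    "IFN-g": (2.6, 0.30),
    "IL-21": (2.4, 0.30),
    "TNF-a": (2.4, 0.30),
    "IL-2": (2.4, 0.30),
    "IL-10": (2.2, 0.30),
    "CXCR5": (2.2, 0.30),
}

_PRESET_CUTOFFS = {
    "PD-1": 0.9,
    "IFN-g": 1.4,
    "IL-21": 1.3,
    "TNF-a": 1.3,
    "IL-2": 1.3,
    "IL-10": 1.2,
    "CXCR5": 1.2,
}
_PRESET_HI_CUTOFFS = {"PD-1": 2.4}


def _pop(name: str, fraction: float, **modes: str) -> PopulationSpec:
    locs, scales = {}, {}
    for marker, mode in modes.items():
        marker = marker.replace("_", "-")  # kwargs cannot contain '-'
        loc, sc = _POSITIVE_MODES[mode]
        locs[marker] = loc
        scales[marker] = sc
    return PopulationSpec(name=name, fraction=fraction, locations=locs, scales=scales)


def lupus_like_preset(n_events: int, seed: int) -> CohortSpec:
    """Five-population memory T-cell cohort with a planted polyfunctional subset.

    Populations (fractions chosen to echo a diseased-mouse spleen where the
    bulk is non-producing and each producing subset is a few percent to ~10%
    of memory cells):

    - ``bulk`` (62%): non-producers, every marker at baseline.
    - ``pd1hi_il10`` (12%): PD-1-hi, IL-10-enriched, IFN-g negative.
    - ``tfh_like`` (10%): PD-1-hi, CXCR5-positive.
    - ``pd1hi_th1`` (8%): PD-1-hi, IFN-g-positive, IL-21 negative.
    - ``super_functional`` (8%): PD-1-low, IFN-g-hi, IL-21/TNF-a/IL-2
      positive, CXCR5 negative — the planted pattern.
    """
    if n_events < 1:
        raise ConfigError(f"n_events must be >= 1, got {n_events}")
    populations = (
        _pop("bulk", 0.62),
        _pop("pd1hi_il10", 0.12, PD_1="PD-1_hi", IL_10="IL-10"),
        _pop("tfh_like", 0.10, PD_1="PD-1_hi", CXCR5="CXCR5"),
        _pop("pd1hi_th1", 0.08, PD_1="PD-1_hi", IFN_g="IFN-g"),
        _pop(
            "super_functional",
            0.08,
            PD_1="PD-1_low",
            IFN_g="IFN-g",
            IL_21="IL-21",
            TNF_a="TNF-a",
            IL_2="IL-2",
        ),
    )
    return CohortSpec(
        n_events=n_events,
        markers=LUPUS_MARKERS,
        populations=populations,
        noise_scale=0.05,
        seed=seed,
    )


def lupus_like_cutoffs() -> CutoffSet:
    """Positivity cutoffs placed between the preset's modes (as FMO controls
    would place them), plus the PD-1 hi-cutoff for the neg/low/hi trichotomy."""
    return CutoffSet(cutoffs=dict(_PRESET_CUTOFFS), hi_cutoffs=dict(_PRESET_HI_CUTOFFS))


def lupus_planted_region() -> dict:
    """Ground-truth region of the planted subset on the PD-1 x IFN-g plane:
    PD-1 positive but below the hi-cutoff, IFN-g above its cutoff."""
    return {
        "x_marker": "PD-1",
        "y_marker": "IFN-g",
        "x_range": (_PRESET_CUTOFFS["PD-1"], _PRESET_HI_CUTOFFS["PD-1"]),
        "y_min": _PRESET_CUTOFFS["IFN-g"],
        "population": "super_functional",
    }


def expected_positive_fraction(spec: CohortSpec, marker: str, cutoff: float) -> float:
    """Analytic mixture probability that ``marker`` exceeds ``cutoff``.

    Valid for cutoffs above the truncation floor (clipping then cannot move
    mass across the cutoff).  The acquisition noise adds in quadrature to
    each population's scale.
    """
    if cutoff <= spec.floor:
        raise ConfigError("expected fraction undefined for cutoffs at/below floor")
    p = 0.0
    for pop in spec.populations:
        sigma = float(np.hypot(pop.scale(marker), spec.noise_scale))
        mu = pop.location(marker)
        if sigma == 0:
            tail = 1.0 if mu > cutoff else 0.0
        else:
            tail = float(norm.sf(cutoff, loc=mu, scale=sigma))
        p += pop.fraction * tail
    return p


# ---------------------------------------------------------------------------
# YAML serialization (generate(spec) == generate(parse(serialize(spec))))

def cohort_to_yaml(spec: CohortSpec) -> str:
    doc = {
        "n_events": spec.n_events,
        "markers": list(spec.markers),
        "noise_scale": spec.noise_scale,
        "floor": spec.floor,
        "seed": spec.seed,
        "populations": [
            {
                "name": p.name,
                "fraction": p.fraction,
                "locations": dict(p.locations),
                "scales": dict(p.scales),
                **(
                    {"correlation": [list(r) for r in p.correlation]}
                    if p.correlation is not None
                    else {}
                ),
            }
            for p in spec.populations
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def cohort_from_yaml(text: str) -> CohortSpec:
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid cohort YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError("cohort YAML must be a mapping")
    try:
        populations = tuple(
            PopulationSpec(
                name=p["name"],
                fraction=float(p["fraction"]),
                locations={k: float(v) for k, v in p.get("locations", {}).items()},
                scales={k: float(v) for k, v in p.get("scales", {}).items()},
                correlation=p.get("correlation"),
            )
            for p in doc["populations"]
        )
        return CohortSpec(
            n_events=int(doc["n_events"]),
            markers=tuple(doc["markers"]),
            populations=populations,
            noise_scale=float(doc.get("noise_scale", 0.0)),
            floor=float(doc.get("floor", -0.5)),
            seed=int(doc.get("seed", 0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid cohort spec: {exc}") from exc
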