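"""Configuration objects for simulation and pipeline runs.

Both configs serialize to a flat ``key = value`` text format (one field per
line; mapping-valued fields carry a JSON literal). The era table is the
sensor-delimited analysis window of the study design: E1 = Landsat 5,
1990-2011 and E2 = Landsat 8, 2013-2024; 2012 belongs to neither era.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .errors import ConfigurationError

#: Calendar months of the growing-season observation window (May-September).
GROWING_SEASON_MONTHS = (5, 6, 7, 8, 9)

#: Cluster quadrant labels used throughout: sign of (greening slope, variance slope).
CLUSTER_LABELS = {
    "A": "A_intensification",      # (+, -) homogenizing, greening gardens
    "B": "B_naturalization",       # (+, +) re-vegetating, diversifying
    "C": "C_artificialization",    # (-, -) sealing / green-feature loss
    "D": "D_ruralization",         # (-, +) variable private farming use
}
NO_LABEL = "none"


@dataclass(frozen=True)
class EraDefinition:
    """One sensor-delimited analysis window (closed year range)."""

    sensor: str
    year_start: int
    year_end: int

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1


def default_eras() -> dict[str, EraDefinition]:
    return {
        "E1": EraDefinition("L5", 1990, 2011),
        "E2": EraDefinition("L8", 2013, 2024),
    }


@dataclass
class SimulationConfig:
    """Stated world for the synthetic scene generator.

    Defaults describe a Brandenburg-like village landscape: gardens and
    abandoned-land-use references scattered within 1 km of village centers, a
    shared background greening trend, a mid-summer-peaking seasonal NDVI curve
    sampled May-September, and garden-specific deviations in season-mean slope
    (delta, NDVI/yr) and within-season-variance slope (gamma, var-units/yr)
    drawn per cluster label.
    """

    n_gardens: int = 200
    n_references: int = 50
    n_villages: int = 5
    #: decoy gardens placed farther than village_radius from every village
    n_decoy_gardens: int = 0
    domain_extent: float = 10_000.0
    #: planar offset so coordinates resemble a projected national grid
    origin_x: float = 3_300_000.0
    origin_y: float = 5_700_000.0
    village_radius: float = 1000.0
    year_start: int = 1990
    year_end: int = 2024
    #: mean Poisson count of growing-season observations per centroid-year
    obs_per_season: float = 8.0
    baseline_mean: float = 0.5
    seasonal_amplitude: float = 0.15
    #: shared background greening trend beta_bg, NDVI/yr
    background_mean_slope: float = 0.002
    #: shared background within-season-variance trend gamma_bg, var-units/yr
    background_var_slope: float = 1.0e-5
    garden_mean_slope_by_cluster: dict[str, float] = field(
        default_factory=lambda: {"A": 0.005, "B": 0.005, "C": -0.005, "D": -0.005, "null": 0.0}
    )
    garden_var_slope_by_cluster: dict[str, float] = field(
        default_factory=lambda: {"A": -5e-4, "B": 5e-4, "C": -5e-4, "D": 5e-4, "null": 0.0}
    )
    cluster_mix: dict[str, float] = field(
        default_factory=lambda: {"A": 0.1, "B": 0.1, "C": 0.1, "D": 0.1, "null": 0.6}
    )
    #: i.i.d. observation noise sd at the first year, NDVI units
    noise_sd: float = 0.05
    #: probability that any single observation is missing (cloud, QA loss)
    missing_rate: float = 0.1
    #: also emit October-April observations (off by default; the analysis window
    #: is May-September and the pipeline filters them out anyway)
    emit_off_season: bool = False
    #: clip emitted NDVI to [-1, 1] (disable only for expectation checks)
    clip: bool = True
    #: variance floor factor keeping sigma^2 positive under strongly negative gamma
    epsilon_floor: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_gardens <= 0 or self.n_references <= 0 or self.n_villages <= 0:
            raise ConfigurationError("n_gardens, n_references and n_villages must be positive")
        if self.n_decoy_gardens < 0:
            raise ConfigurationError("n_decoy_gardens must be >= 0")
        if self.village_radius <= 0:
            raise ConfigurationError("village_radius must be positive")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if self.year_end < self.year_start:
            raise ConfigurationError("year_end must be >= year_start")
        total = sum(self.cluster_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"cluster_mix proportions must sum to 1 (got {total!r})"
            )
        unknown = set(self.cluster_mix) - (set(CLUSTER_LABELS) | {"null"})
        if unknown:
            raise ConfigurationError(f"unknown cluster_mix labels: {sorted(unknown)}")
        eras = default_eras()
        if not any(
            e.year_start <= self.year_end and self.year_start <= e.year_end
            for e in eras.values()
        ):
            raise ConfigurationError("year range must intersect at least one sensor era")


@dataclass
class PipelineConfig:
    """Tunable parameters of the analysis pipeline.

    alpha is the per-fit two-sided significance level (strict ``p < alpha``);
    no multiple-testing correction is applied, matching the study design, and
    the summary reports how many tests were run so users can post-correct.
    """

    alpha: float = 0.05
    village_radius: float = 1000.0
    min_obs_per_season: int = 3
    min_years_per_era: int = 5
    #: "fitted_line": subtract the reference's fitted OLS line (tolerates
    #: mismatched year sets); "paired_values": subtract raw reference season
    #: metrics on common years.
    detrend_mode: str = "fitted_line"
    #: "propagate": the detrended-slope test combines garden and reference
    #: slope standard errors (Welch df) so the null rejection rate is the
    #: nominal alpha; "ignore": plain OLS p of the adjusted series, which
    #: ignores the reference-fit error and inflates the null rate ~3x.
    #: Only meaningful for detrend_mode="fitted_line".
    reference_uncertainty: str = "propagate"
    variance_divisor: str = "n_minus_1"  # or "n"
    #: "none": gardens whose paired reference lacks a fittable series get an
    #: insufficient-data outcome; "regional_mean": fall back to the mean
    #: reference trend of the era.
    background_fallback: str = "none"
    max_pair_distance: Optional[float] = None
    #: pair gardens to references before (True) or after (False) the village
    #: radius filter
    pair_before_filter: bool = False
    eras: dict[str, EraDefinition] = field(default_factory=default_eras)
    centroids_path: Optional[str] = None
    observations_path: Optional[str] = None
    out_dir: Optional[str] = None
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigurationError("alpha must lie in (0, 1]")
        if self.village_radius <= 0:
            raise ConfigurationError("village_radius must be positive")
        if self.min_obs_per_season < 2:
            raise ConfigurationError("min_obs_per_season must be >= 2 (variance needs n >= 2)")
        if self.min_years_per_era < 3:
            raise ConfigurationError("min_years_per_era must be >= 3 (t-test needs df >= 1)")
        if self.detrend_mode not in ("fitted_line", "paired_values"):
            raise ConfigurationError(f"unknown detrend_mode {self.detrend_mode!r}")
        if self.reference_uncertainty not in ("propagate", "ignore"):
            raise ConfigurationError(f"unknown reference_uncertainty {self.reference_uncertainty!r}")
        if self.variance_divisor not in ("n_minus_1", "n"):
            raise ConfigurationError(f"unknown variance_divisor {self.variance_divisor!r}")
        if self.background_fallback not in ("none", "regional_mean"):
            raise ConfigurationError(f"unknown background_fallback {self.background_fallback!r}")
        spans = sorted((e.year_start, e.year_end) for e in self.eras.values())
        for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ConfigurationError("era year ranges must be disjoint")


# ---------------------------------------------------------------------------
# flat key = value config files
# ---------------------------------------------------------------------------

def _encode_value(value) -> str:
    if isinstance(value, dict):
        if value and isinstance(next(iter(value.values())), EraDefinition):
            value = {k: [v.sensor, v.year_start, v.year_end] for k, v in value.items()}
        return json.dumps(value, sort_keys=True)
    if value is None:
        return "null"
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def write_config(cfg, path) -> None:
    """Write a config dataclass as flat ``key = value`` lines."""
    lines = [
        f"{f.name} = {_encode_value(getattr(cfg, f.name))}"
        for f in dataclasses.fields(cfg)
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _coerce(name: str, raw: str, ftype):
    raw = raw.strip()
    if raw == "null":
        return None
    if raw in ("true", "false"):
        return raw == "true"
    if raw.startswith(("{", "[")):
        value = json.loads(raw)
        if name == "eras":
            return {k: EraDefinition(v[0], int(v[1]), int(v[2])) for k, v in value.items()}
        return value
    for caster in (int, float):
        try:
            return caster(raw)
        except ValueError:
            pass
    return raw


def read_config(path, cls):
    """Read a flat key = value file into a config dataclass of type ``cls``."""
    known = {f.name: f.type for f in dataclasses.fields(cls)}
    kwargs = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigurationError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        name, raw = (part.strip() for part in line.split("=", 1))
        if name not in known:
            raise ConfigurationError(f"{path}:{lineno}: unknown field {name!r} for {cls.__name__}")
        kwargs[name] = _coerce(name, raw, known[name])
    cfg = cls(**kwargs)
    cfg.validate()
    return cfg
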