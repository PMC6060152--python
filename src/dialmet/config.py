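"""Study design, run configuration and logging for the microdialysis pipeline.

The experiment this package analyses follows a fixed template: mice carry
microdialysis probes in two cortical regions and are sampled in 15-minute
bins for ~10 hours.  The first two hours are spent awake on a slow treadmill
and the five bins spanning the end of hour 1 plus hour 2 serve as the
per-mouse reference (baseline) window; the remaining 9 hours are spent in a
group-specific sleep/wake schedule.  :class:`StudyDesign` encodes that
template, :class:`RunConfig` the tunable stage parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

log = logging.getLogger("dialmet")

SLEEP = "sleep"
WAKE = "wake"

#: canonical EEG band identifiers (Hz ranges in the names)
BAND_LOW = "low_2_6"
BAND_SWA = "swa_0p5_4"
BAND_GAMMA = "gamma_40_100"
BANDS = (BAND_LOW, BAND_SWA, BAND_GAMMA)


class SchemaError(ValueError):
    """A table or design violates its declared schema."""


class IntegrityError(ValueError):
    """Data are structurally inconsistent (duplicates, missing companions)."""


@dataclass(frozen=True)
class GroupSpec:
    """One experimental arm: name, cohort size and post-reference schedule.

    ``schedule`` is a sequence of ``(n_bins, state)`` segments covering the
    9 experimental hours (36 bins at 15 min).
    """

    name: str
    n_mice: int
    schedule: tuple[tuple[int, str], ...]

    def scheduled_states(self) -> list[str]:
        out: list[str] = []
        for n, state in self.schedule:
            if state not in (SLEEP, WAKE):
                raise SchemaError(f"unknown state {state!r} in group {self.name}")
            out.extend([state] * n)
        return out


@dataclass(frozen=True)
class StudyDesign:
    groups: tuple[GroupSpec, ...]
    regions: tuple[str, ...] = ("mPFC", "M1")
    n_reference_bins: int = 5
    bins_per_mouse: int = 41
    bin_minutes: int = 15
    coarse_factor: int = 4
    lights_on: str = "08:00"
    lights_off: str = "20:00"

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise SchemaError("group names must be unique")
        n_exp = self.bins_per_mouse - self.n_reference_bins
        if n_exp <= 0 or n_exp % self.coarse_factor:
            raise SchemaError(
                "experimental bins must be a positive multiple of coarse_factor"
            )
        for g in self.groups:
            states = g.scheduled_states()
            if len(states) != n_exp:
                raise SchemaError(
                    f"group {g.name}: schedule covers {len(states)} bins, "
                    f"expected {n_exp}"
                )

    # -- derived geometry -------------------------------------------------
    @property
    def n_hours(self) -> int:
        return (self.bins_per_mouse - self.n_reference_bins) // self.coarse_factor

    @property
    def n_mice(self) -> int:
        return sum(g.n_mice for g in self.groups)

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.groups)

    def group(self, name: str) -> GroupSpec:
        for g in self.groups:
            if g.name == name:
                return g
        raise SchemaError(f"unknown group {name!r}")

    def is_reference_bin(self, bin_index: int) -> bool:
        return 0 <= bin_index < self.n_reference_bins

    def hour_of_bin(self, bin_index: int) -> int:
        """1-based experimental hour of a post-reference bin (0 = reference)."""
        if self.is_reference_bin(bin_index):
            return 0
        return (bin_index - self.n_reference_bins) // self.coarse_factor + 1

    def scheduled_state(self, group: str, bin_index: int) -> str:
        """Scheduled behavioral state for a bin (reference bins are wake)."""
        if self.is_reference_bin(bin_index):
            return WAKE
        return self.group(group).scheduled_states()[bin_index - self.n_reference_bins]

    def mouse_ids(self) -> dict[str, list[str]]:
        """Deterministic mouse identifiers per group (m01, m02, ...)."""
        ids: dict[str, list[str]] = {}
        counter = 0
        for g in self.groups:
            ids[g.name] = [f"m{counter + i + 1:02d}" for i in range(g.n_mice)]
            counter += g.n_mice
        return ids


def default_design() -> StudyDesign:
    """The three-arm design: S6-EW3 (n=7), EW6-S3 (n=6), SW6-EW3 (n=6).

    41 bins of 15 min per mouse: 5 reference bins on the treadmill, then
    6 h + 3 h segments (24 + 12 bins) in the group's schedule.
    """
    return StudyDesign(
        groups=(
            GroupSpec("S6-EW3", 7, ((24, SLEEP), (12, WAKE))),
            GroupSpec("EW6-S3", 6, ((24, WAKE), (12, SLEEP))),
            GroupSpec("SW6-EW3", 6, ((24, WAKE), (12, WAKE))),
        )
    )


@dataclass
class RunConfig:
    """Stage parameters for the full pipeline.

    Defaults follow the analysis conventions this pipeline implements:
    detection in >=3 mice per condition, 5x outlier rule, >50% wrong-state
    exclusion, 4-bin coarse-graining, k=2 nearest-hour imputation, feature
    matching at 0.0014 Da / 0.3 min, alpha=0.05, l2 logistic with C=0.001,
    100x repeated stratified 3-fold CV, BH at q=0.05.
    """

    inputs: dict = field(default_factory=dict)
    seed: int = 0
    outlier_factor: float = 5.0
    min_mice: int = 3
    wrong_state_threshold: float = 0.5
    coarse_factor: int = 4
    knn_k: int = 2
    mass_tol: float = 0.0014
    rt_tol: float = 0.3
    alpha: float = 0.05
    C: float = 0.001
    cv_folds: int = 3
    cv_reps: int = 100
    n_permutations: int = 1000
    perm_reps: int = 10
    fdr_q: float = 0.05
    n_components: int = 2
    v_tol: float = 1e-6
    c_tol: float = 0.99

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def setup_logging(level: int = logging.INFO) -> None:
    if not log.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        log.addHandler(h)
    log.setLevel(level)
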