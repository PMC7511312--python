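"""Seeded generators for every input the pipeline consumes.

No raw data accompany the study conditions this package models, so each
wet-lab readout is emulated by a generator with planted ground truth:

* bright-field RGB micrographs — cells as anti-aliased disks on a bright
  background; inside a cell, astaxanthin attenuates the green channel and
  chlorophyll the red channel (both attenuate blue, as photosynthetic
  pigments do); dead cells carry an additional stain absorbance that is
  spectrally flat across red and green, so staining shifts both channels
  equally and leaves the green-minus-red pigment score of a cell untouched
  while making blue dominant for the classifier;
* Ct tables — a full 3 biological x 3 technical design per gene, condition
  and timepoint, with ``Ct = baseCt(gene) - log2(fold) + N(0, sd)`` and a
  constant-up-to-noise housekeeping gene;
* count tables — stained cells drawn Binomial(total, p) per experimental
  series.

Scenario presets encode the reported effect structure of the study
conditions as point parameters (e.g. "around twofold" -> 2.0): mortality
trajectories (control < 3%, stringent 50 ns pulses 14 -> 19%, moderate
25 ns pulses ~6% then rising to 17%), transcript fold changes (50 ns peak
~2x at 72 h; 25 ns crtR-b repression to ~1/3; DPI doubling; calcium-influx
modulation), and astaxanthin attenuation levels. These are emulation
targets for parameter-recovery testing, not measurements.

Determinism: a single integer seed fans out to per-artefact child seeds via
``numpy.random.SeedSequence`` spawn keys, so each artefact is independently
and byte-for-byte reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "GENES",
    "HOUSEKEEPING_GENE",
    "TIMEPOINTS_H",
    "ScenarioConfig",
    "SyntheticTruth",
    "child_rng",
    "generate_micrograph",
    "generate_ct_table",
    "generate_counts",
    "preset_scenarios",
]

GENES = ("psy", "crtR-b", "bkt 1")
HOUSEKEEPING_GENE = "actin"
TIMEPOINTS_H = (18.0, 24.0, 48.0, 72.0, 96.0)

#: Baseline cycle-threshold per gene (cycles) for the Ct generator.
BASE_CT = {"psy": 24.0, "crtR-b": 26.0, "bkt 1": 25.0, HOUSEKEEPING_GENE: 18.0}

# image-formation constants (8-bit intensities)
_BACKGROUND = 230.0
_BLUE_ABSORPTION = 0.6  # blue attenuation per unit of (astaxanthin + chlorophyll)
_STAIN_DEPTH = 100.0  # additive stain absorbance on R and G of dead cells
_STAIN_BLUE = 0.05  # small blue absorbance of the stain, x background
_CHL_MEAN, _CHL_SD = 0.45, 0.02
_AST_SD = 0.08
_AST_MAX = 0.56  # keeps stained-cell green channel non-negative (no clipping)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameter bundle for one treatment condition.

    ``mortality_pct`` maps timepoint (h) to the true stained fraction in
    percent; ``log2_fold`` maps gene -> timepoint -> true log2 fold change
    relative to the baseline sample; ``astaxanthin_level`` is the mean
    per-cell green-channel attenuation (0-1). ``baseline_timepoint_h``
    names the control timepoint the fold changes refer to (18 h for the
    time-course family, 72 h for the inhibitor family).
    """

    name: str
    condition: str
    mortality_pct: Mapping[float, float]
    log2_fold: Mapping[str, Mapping[float, float]]
    astaxanthin_level: float
    ct_sd: float = 0.2
    image_noise_sd: float = 2.0
    n_bio: int = 3
    n_tech: int = 3
    cells_per_count: int = 1500
    baseline_timepoint_h: float = 18.0

    def __post_init__(self) -> None:
        for tp, m in self.mortality_pct.items():
            if not (0.0 <= m <= 100.0):
                raise ValidationError(f"mortality {m}% at {tp} h out of [0, 100]")
        if not (0.0 <= self.astaxanthin_level <= 1.0):
            raise ValidationError("astaxanthin_level must lie in [0, 1]")
        if self.ct_sd < 0 or self.image_noise_sd < 0:
            raise ValidationError("noise standard deviations must be non-negative")
        if self.n_bio < 1 or self.n_tech < 1 or self.cells_per_count < 1:
            raise ValidationError("replicate design counts must be positive")

    @property
    def timepoints_h(self) -> Tuple[float, ...]:
        tps = set(self.mortality_pct) | {
            tp for by_tp in self.log2_fold.values() for tp in by_tp
        }
        return tuple(sorted(tps))

    def fold(self, gene: str, timepoint_h: float) -> float:
        """Linear planted fold change (1.0 where none is specified)."""
        return float(2.0 ** self.log2_fold.get(gene, {}).get(timepoint_h, 0.0))


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying one generated artefact."""

    kind: str
    scenario: str
    seed: int
    cells: List[dict] = field(default_factory=list)
    true_folds: Dict[str, Dict[str, float]] = field(default_factory=dict)
    true_mortality_pct: Dict[str, float] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def child_rng(seed: int, *tags: Union[str, int]) -> np.random.Generator:
    """Deterministic child generator for one artefact.

    Tags (strings or ints) are hashed into a ``SeedSequence`` spawn key, so
    artefacts drawn from the same master seed are independent yet each is
    reproducible on its own.
    """
    key = tuple(
        t if isinstance(t, int) else zlib.crc32(str(t).encode()) for t in tags
    )
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _place_cells(
    rng: np.random.Generator,
    n_cells: int,
    shape: Tuple[int, int],
    radius_px_range: Tuple[float, float],
    max_attempts: int = 10_000,
) -> List[Tuple[float, float, float]]:
    """Dart-throwing placement of non-overlapping disks fully inside the frame."""
    h, w = shape
    placed: List[Tuple[float, float, float]] = []
    attempts = 0
    while len(placed) < n_cells and attempts < max_attempts:
        attempts += 1
        r = rng.uniform(*radius_px_range)
        if 2 * r + 6 > min(h, w):
            continue
        y = rng.uniform(r + 3, h - r - 3)
        x = rng.uniform(r + 3, w - r - 3)
        if all((y - y0) ** 2 + (x - x0) ** 2 > (r + r0 + 2) ** 2 for y0, x0, r0 in placed):
            placed.append((y, x, r))
    return placed


def generate_micrograph(
    cfg: ScenarioConfig,
    seed: int,
    *,
    timepoint_h: Optional[float] = None,
    n_cells: int = 12,
    shape: Tuple[int, int] = (768, 768),
    um_per_px: float = 0.5,
    radius_um_range: Tuple[float, float] = (8.0, 50.0),
) -> Tuple[np.ndarray, SyntheticTruth]:
    """One synthetic bright-field micrograph plus its planted truth.

    Cell radii are drawn uniformly over the 8-50 um range typical of the
    organism, scaled by ``um_per_px``. Each cell carries a planted
    astaxanthin attenuation ~ N(level, 0.08) and chlorophyll attenuation
    ~ N(0.45, 0.02); it is dead with the scenario's mortality probability
    at ``timepoint_h`` (default: the scenario's last timepoint). Gaussian
    pixel noise is added and the image quantised to 8 bits.
    """
    if timepoint_h is None:
        tps = cfg.timepoints_h
        timepoint_h = tps[-1] if tps else 72.0
    p_dead = cfg.mortality_pct.get(timepoint_h, 0.0) / 100.0
    rng = child_rng(seed, "micrograph", cfg.name, int(timepoint_h * 10))

    r_px = (radius_um_range[0] / um_per_px, radius_um_range[1] / um_per_px)
    placed = _place_cells(rng, n_cells, shape, r_px)

    channels = np.full((3,) + shape, _BACKGROUND, dtype=float)
    truth = SyntheticTruth(kind="micrograph", scenario=cfg.name, seed=seed)
    for y, x, r in placed:
        ast = float(np.clip(rng.normal(cfg.astaxanthin_level, _AST_SD), 0.0, _AST_MAX))
        chl = float(np.clip(rng.normal(_CHL_MEAN, _CHL_SD), 0.0, 0.52))
        dead = bool(rng.random() < p_dead)

        lo_r, hi_r = int(np.floor(y - r - 1)), int(np.ceil(y + r + 2))
        lo_c, hi_c = int(np.floor(x - r - 1)), int(np.ceil(x + r + 2))
        rows = np.arange(max(lo_r, 0), min(hi_r, shape[0]))
        cols = np.arange(max(lo_c, 0), min(hi_c, shape[1]))
        dist = np.sqrt((rows[:, None] - y) ** 2 + (cols[None, :] - x) ** 2)
        cov = np.clip(r + 0.5 - dist, 0.0, 1.0)  # anti-aliased edge

        absorb_r = _BACKGROUND * chl + (_STAIN_DEPTH if dead else 0.0)
        absorb_g = _BACKGROUND * ast + (_STAIN_DEPTH if dead else 0.0)
        absorb_b = _BACKGROUND * _BLUE_ABSORPTION * min(1.0, ast + chl) + (
            _BACKGROUND * _STAIN_BLUE if dead else 0.0
        )
        sl = np.ix_(rows, cols)
        channels[0][sl] -= cov * absorb_r
        channels[1][sl] -= cov * absorb_g
        channels[2][sl] -= cov * absorb_b

        truth.cells.append(
            {
                "y": y,
                "x": x,
                "radius_px": r,
                "astaxanthin": ast,
                "chlorophyll": chl,
                "dead": dead,
            }
        )
    truth.true_mortality_pct[str(timepoint_h)] = 100.0 * p_dead

    img = np.moveaxis(channels, 0, -1)
    if cfg.image_noise_sd > 0:
        img = img + rng.normal(0.0, cfg.image_noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, truth


def generate_ct_table(
    cfgs: Union[ScenarioConfig, Sequence[ScenarioConfig]],
    seed: int,
    *,
    baseline_condition: str = "control",
) -> Tuple[pd.DataFrame, SyntheticTruth]:
    """Tidy Ct table with a full replicate design and planted fold changes.

    ``Ct = baseCt(gene) - log2(fold) + N(0, ct_sd)`` per technical
    measurement; the housekeeping gene is constant across conditions up to
    the same noise. Baseline-condition rows (fold 1) are added when no
    supplied scenario is labelled ``baseline_condition``, so the table is
    always normalisable.
    """
    if isinstance(cfgs, ScenarioConfig):
        cfgs = [cfgs]
    if not cfgs:
        raise ValidationError("at least one scenario is required")
    lead = cfgs[0]
    timepoints = sorted({tp for cfg in cfgs for tp in cfg.timepoints_h} or {lead.baseline_timepoint_h})
    if lead.baseline_timepoint_h not in timepoints:
        timepoints = sorted(set(timepoints) | {lead.baseline_timepoint_h})

    conditions: List[Tuple[str, Optional[ScenarioConfig]]] = []
    if not any(cfg.condition == baseline_condition for cfg in cfgs):
        conditions.append((baseline_condition, None))
    conditions.extend((cfg.condition, cfg) for cfg in cfgs)

    rng = child_rng(seed, "ct", *(cfg.name for cfg in cfgs))
    truth = SyntheticTruth(kind="ct_table", scenario=",".join(cfg.name for cfg in cfgs), seed=seed)
    rows = []
    for condition, cfg in conditions:
        sd = cfg.ct_sd if cfg is not None else lead.ct_sd
        n_bio = cfg.n_bio if cfg is not None else lead.n_bio
        n_tech = cfg.n_tech if cfg is not None else lead.n_tech
        for tp in timepoints:
            for gene in GENES + (HOUSEKEEPING_GENE,):
                if gene == HOUSEKEEPING_GENE or cfg is None:
                    fold = 1.0
                else:
                    fold = cfg.fold(gene, tp)
                if gene != HOUSEKEEPING_GENE:
                    truth.true_folds.setdefault(gene, {})[f"{condition}@{tp}"] = fold
                mean_ct = BASE_CT[gene] - np.log2(fold)
                for bio in range(1, n_bio + 1):
                    for tech in range(1, n_tech + 1):
                        ct = mean_ct + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                        rows.append(
                            {
                                "gene": gene,
                                "condition": condition,
                                "timepoint_h": tp,
                                "bio_rep": bio,
                                "tech_rep": tech,
                                "ct": ct,
                            }
                        )
    return pd.DataFrame(rows), truth


def generate_counts(
    cfg: ScenarioConfig,
    seed: int,
    *,
    n_series: int = 3,
) -> Tuple[pd.DataFrame, SyntheticTruth]:
    """Count table: stained ~ Binomial(total, p) per timepoint and series.

    ``total`` is the scenario's ``cells_per_count`` (>= 1500 by default in
    presets) for every series.
    """
    rng = child_rng(seed, "counts", cfg.name)
    truth = SyntheticTruth(kind="counts", scenario=cfg.name, seed=seed)
    rows = []
    for tp in sorted(cfg.mortality_pct):
        p = cfg.mortality_pct[tp] / 100.0
        truth.true_mortality_pct[str(tp)] = cfg.mortality_pct[tp]
        for series in range(1, n_series + 1):
            total = cfg.cells_per_count
            stained = int(rng.binomial(total, p))
            rows.append(
                {
                    "sample_id": f"{cfg.condition}-t{tp:g}-s{series}",
                    "condition": cfg.condition,
                    "timepoint_h": tp,
                    "total_cells": total,
                    "stained_cells": stained,
                }
            )
    return pd.DataFrame(rows), truth


def _timecourse(values: Mapping[float, float]) -> Dict[float, float]:
    return {float(k): float(np.log2(v)) for k, v in values.items()}


def preset_scenarios() -> Dict[str, ScenarioConfig]:
    """Scenario bundle encoding the reported study conditions.

    Twelve presets: 3 pulse conditions (control, 25 ns, 50 ns) x 4
    inhibitor states (none, +DPI, +A23187, +GdCl3). The no-inhibitor family
    carries the full 18-96 h time course (fold changes relative to the
    untreated control at 18 h); the inhibitor families are single-timepoint
    (72 h) designs normalised to the untreated, un-pulsed control at 72 h,
    matching how those experiments were reported (their values are not
    comparable to the time-course normalisation).
    """
    flat = {tp: 1.0 for tp in TIMEPOINTS_H}

    presets = {
        "control": ScenarioConfig(
            name="control",
            condition="control",
            mortality_pct={tp: 2.0 for tp in TIMEPOINTS_H},
            log2_fold={g: _timecourse(flat) for g in GENES},
            astaxanthin_level=0.30,
        ),
        "25ns": ScenarioConfig(
            name="25ns",
            condition="25ns",
            # moderate pulses: ~6% plateau to 48 h, then a sharp rise to 17%
            mortality_pct={18.0: 7.0, 24.0: 6.5, 48.0: 6.0, 72.0: 12.0, 96.0: 17.0},
            log2_fold={
                "psy": _timecourse({18.0: 1, 24.0: 1, 48.0: 1, 72.0: 0.6, 96.0: 0.6}),
                "crtR-b": _timecourse({18.0: 1, 24.0: 1, 48.0: 1, 72.0: 1 / 3, 96.0: 1 / 3}),
                "bkt 1": _timecourse(flat),
            },
            astaxanthin_level=0.33,
        ),
        "50ns": ScenarioConfig(
            name="50ns",
            condition="50ns",
            # stringent pulses: mortality nearly complete at 18 h, creeping to 19%
            mortality_pct={18.0: 14.0, 24.0: 15.0, 48.0: 16.0, 72.0: 17.0, 96.0: 19.0},
            log2_fold={
                "psy": _timecourse({18.0: 1, 24.0: 1, 48.0: 1.4, 72.0: 2.0, 96.0: 1.2}),
                "crtR-b": _timecourse({18.0: 1, 24.0: 1, 48.0: 1.4, 72.0: 2.0, 96.0: 1.2}),
                "bkt 1": _timecourse({18.0: 1, 24.0: 1, 48.0: 1.4, 72.0: 2.2, 96.0: 1.2}),
            },
            astaxanthin_level=0.31,
        ),
    }

    def inhibitor(name, condition, mortality, folds, ast):
        return ScenarioConfig(
            name=name,
            condition=condition,
            mortality_pct={72.0: mortality},
            log2_fold={g: _timecourse({72.0: folds[g]}) for g in GENES},
            astaxanthin_level=ast,
            baseline_timepoint_h=72.0,
        )

    # DPI (NADPH-oxidase inhibitor): roughly doubles transcripts in the
    # un-pulsed control; astaxanthin +30% (control, 50 ns) and +80% (25 ns).
    presets["control+DPI"] = inhibitor(
        "control+DPI", "control+DPI", 2.5,
        {"psy": 2.0, "crtR-b": 2.0, "bkt 1": 2.0}, 0.39,
    )
    presets["25ns+DPI"] = inhibitor(
        "25ns+DPI", "25ns+DPI", 8.0,
        {"psy": 2.6, "crtR-b": 2.6, "bkt 1": 2.6}, 0.54,
    )
    presets["50ns+DPI"] = inhibitor(
        "50ns+DPI", "50ns+DPI", 15.0,
        {"psy": 2.6, "crtR-b": 2.6, "bkt 1": 2.6}, 0.39,
    )
    # A23187 (calcium ionophore): sufficient to induce psy alone; with 25 ns
    # also crtR-b; blunts the bkt 1 response to 50 ns.
    presets["control+A23187"] = inhibitor(
        "control+A23187", "control+A23187", 2.5,
        {"psy": 1.8, "crtR-b": 1.0, "bkt 1": 1.0}, 0.32,
    )
    presets["25ns+A23187"] = inhibitor(
        "25ns+A23187", "25ns+A23187", 8.0,
        {"psy": 2.0, "crtR-b": 2.0, "bkt 1": 1.0}, 0.33,
    )
    presets["50ns+A23187"] = inhibitor(
        "50ns+A23187", "50ns+A23187", 15.0,
        {"psy": 2.0, "crtR-b": 2.0, "bkt 1": 1.2}, 0.31,
    )
    # GdCl3 (calcium-influx blocker): largely eliminates the pulse response
    # (crtR-b falls from 4x to 2x under 50 ns); astaxanthin reduced ~20%.
    presets["control+GdCl3"] = inhibitor(
        "control+GdCl3", "control+GdCl3", 2.5,
        {"psy": 1.0, "crtR-b": 1.0, "bkt 1": 1.0}, 0.24,
    )
    presets["25ns+GdCl3"] = inhibitor(
        "25ns+GdCl3", "25ns+GdCl3", 8.0,
        {"psy": 1.0, "crtR-b": 1.5, "bkt 1": 1.0}, 0.26,
    )
    presets["50ns+GdCl3"] = inhibitor(
        "50ns+GdCl3", "50ns+GdCl3", 15.0,
        {"psy": 1.3, "crtR-b": 2.0, "bkt 1": 1.0}, 0.25,
    )
    return presets
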