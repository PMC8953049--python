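"""End-to-end study drivers and printed-table verification.

Three reproducible experiment drivers mirror the study designs the
quantification stack was built for:

* a paired rest/stress vasodilation study (brain, n = 6, or left ventricle,
  n = 5) producing one table row per subject plus an exact signed-rank test;
* an infarct-sizing study comparing the Otsu-stratified PET estimate with
  the TTC stain estimate on matched phantoms of known wedge fraction;
* ``reproduce_tables``, which recomputes every derivable cell of the
  published per-rat tables (shipped as CSV fixtures, since the underlying
  images are not deposited) and reports match/mismatch per cell.

All phantom randomness is derived from a single study seed; identical
configs produce byte-identical output tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffimg, infarct, ranktests
from .errors import ValidationError
from .phantom import (
    InfarctSpec,
    PhantomSpec,
    make_brain_phantom,
    make_lv_phantom,
    make_ttc_image,
)

logger = logging.getLogger("vascupet")

RATIO_TOL = 0.01  # printed tables carry two decimals

#: Table cells whose printed value does not reproduce from the same table's
#: own numbers at +/-0.01 (ratio != 100 x difference / rest, or mean/SE !=
#: sample mean/SE of the printed column), plus the n = 5 paired-test
#: significance claims: the exact two-tailed signed-rank p at complete
#: separation of five pairs is 2/32 = 0.0625 > 0.05, so the published
#: "U = 0 <= 2" critical-value reading is not reproducible as an exact
#: p < 0.05.  These cells are reported and flagged, not failed.
KNOWN_INCONSISTENT = {
    ("table2", "ratio_rat2"),
    ("table2", "ratio_rat3"),
    ("table2", "ratio_rat5"),
    ("table2", "control_se"),
    ("table2", "signed_rank_p"),
    ("table3", "ratio_rat1"),
    ("table3", "ratio_rat2"),
    ("table3", "ratio_rat5"),
    ("table3", "signed_rank_p"),
    ("table1", "fdg_mean"),
    ("table1", "fdg_se"),
}

#: Mean +/- SE rows as printed under each table.
PRINTED_SUMMARY = {
    "control_mean": 35.12,
    "control_se": 1.91,
    "diabetic_mean": 18.82,
    "diabetic_se": 2.03,
    "fdg_mean": 26.93,
    "fdg_se": 0.83,
    "rbc_mean": 33.89,
    "rbc_se": 1.56,
    "ttc_mean": 26.02,
    "ttc_se": 1.45,
}


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("vascupet.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_infarct_table() -> pd.DataFrame:
    """Per-rat infarct sizes (%) by FDG PET, blood-pool PET, and TTC stain."""
    return _load_csv("table1_infarct_size.csv")


def load_control_table() -> pd.DataFrame:
    """Per-rat control stress/rest LV activities and increased ratios."""
    return _load_csv("table2_control_vasodilation.csv")


def load_diabetic_table() -> pd.DataFrame:
    """Per-rat diabetic stress/rest LV activities and increased ratios."""
    return _load_csv("table3_diabetic_vasodilation.csv")


# -- vasodilation studies --------------------------------------------------


@dataclass(frozen=True)
class VasodilationStudyConfig:
    """A paired rest/stress experiment over n phantom subjects."""

    organ: str  # "brain" | "lv"
    deltas: tuple[float, ...]
    base_spec: PhantomSpec = PhantomSpec(noise="poisson", dwell_scale=1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.organ not in ("brain", "lv"):
            raise ValidationError(f"organ must be 'brain' or 'lv', got {self.organ!r}")
        if len(self.deltas) < 1:
            raise ValidationError("need at least one subject")


def default_brain_config(seed: int = 0, noise: str = "poisson") -> VasodilationStudyConfig:
    """Six subjects at the cerebrovascular response level of 72.2%."""
    return VasodilationStudyConfig(
        organ="brain",
        deltas=(0.722,) * 6,
        base_spec=PhantomSpec(noise=noise, dwell_scale=1.0),
        seed=seed,
    )


def default_lv_config(seed: int = 0, noise: str = "poisson") -> VasodilationStudyConfig:
    """Five subjects at the intramyocardial response level of 52.3%."""
    return VasodilationStudyConfig(
        organ="lv",
        deltas=(0.523,) * 5,
        base_spec=PhantomSpec(noise=noise, dwell_scale=1.0),
        seed=seed,
    )


def _subject_volumes(spec: PhantomSpec, organ: str):
    """Rest and stress (volume, mask) pairs for one subject."""
    out = {}
    for mode in ("rest", "stress"):
        if organ == "brain":
            out[mode] = make_brain_phantom(spec, mode)
        else:
            ph = make_lv_phantom(spec, mode)
            out[mode] = (ph.diastolic_gate, ph.myocardium_mask)
    return out["rest"], out["stress"]


def run_vasodilation_study(
    config: VasodilationStudyConfig, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, ranktests.RankTestResult]:
    """Run the paired study; returns the per-subject table and the exact
    signed-rank test of stress vs rest activity sums.

    The stress volume is co-registered onto the rest volume (integer
    centroid shift) before subtraction, as with real acquisitions.
    """
    rows = []
    for i, delta in enumerate(config.deltas):
        spec = replace(
            config.base_spec, vasodilation_delta=delta, seed=config.seed * 10007 + i
        )
        logger.info("subject %d: organ=%s delta=%.4f seed=%d", i + 1, config.organ, delta, spec.seed)
        (rest_vol, rest_mask), (stress_vol, stress_mask) = _subject_volumes(spec, config.organ)
        stress_vol, stress_mask, shift = diffimg.register_rigid(
            stress_vol, stress_mask, rest_vol, rest_mask
        )
        res = diffimg.increased_ratio(stress_vol, rest_vol, rest_mask)
        rows.append(
            {
                "subject": i + 1,
                "true_delta": delta,
                "stress_activity": res.stress_sum,
                "rest_activity": res.rest_sum,
                "stress_rest_difference": res.clipped_diff_sum,
                "increased_ratio": res.increased_ratio_pct,
            }
        )
    table = pd.DataFrame(rows)
    test = ranktests.signed_rank_exact(
        table["stress_activity"].to_numpy(), table["rest_activity"].to_numpy()
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / f"vasodilation_{config.organ}.csv", index=False)
    return table, test


# -- infarct study ---------------------------------------------------------


@dataclass(frozen=True)
class InfarctStudyConfig:
    """Matched PET + stain infarct sizing over n phantom subjects."""

    wedge_fractions: tuple[float, ...] = (0.25,) * 6
    base_spec: PhantomSpec = PhantomSpec(noise="poisson", dwell_scale=1.0)
    infarct_activity_scale: float = 0.0
    stain_image_size: int = 256
    seed: int = 0


def default_infarct_config(seed: int = 0) -> InfarctStudyConfig:
    return InfarctStudyConfig(seed=seed)


def run_infarct_study(
    config: InfarctStudyConfig, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Size each subject's infarct by Otsu-stratified PET and by TTC stain.

    Returns the per-subject table and a mean +/- SE summary over subjects
    for both methods.
    """
    rows = []
    for i, wf in enumerate(config.wedge_fractions):
        subject_seed = config.seed * 10007 + i
        spec = replace(
            config.base_spec,
            infarct=InfarctSpec(extent_deg=360.0 * wf, activity_scale=config.infarct_activity_scale),
            seed=subject_seed,
        )
        ph = make_lv_phantom(spec, "rest")
        k = spec.grid_shape[infarct.SHORT_AXIS] // 2
        pet = infarct.infarct_percentage(ph.diastolic_gate, ph.myocardium_mask, k)
        img, _truth = make_ttc_image(
            wedge_fraction=wf, image_size=config.stain_image_size, seed=subject_seed
        )
        stain = infarct.stain_infarct(img)
        rows.append(
            {
                "subject": i + 1,
                "true_wedge_pct": 100.0 * wf,
                "pet_infarct_pct": pet.infarct_pct,
                "stain_infarct_pct": stain.infarct_pct,
            }
        )
    table = pd.DataFrame(rows)
    summary_rows = []
    for col in ("pet_infarct_pct", "stain_infarct_pct"):
        mean, se = ranktests.mean_se(table[col])
        summary_rows.append({"method": col, "mean": mean, "se": se})
    summary = pd.DataFrame(summary_rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "infarct_study.csv", index=False)
        summary.to_csv(out / "infarct_study_summary.csv", index=False)
    return table, summary


# -- printed-table verification --------------------------------------------


def reproduce_tables() -> pd.DataFrame:
    """Recompute every derivable cell of the published tables.

    Each row reports the printed value, the value recomputed from the same
    table's raw numbers (ratio = 100 x difference / rest; mean and SE of the
    printed columns; exact rank statistics), the comparison rule, and
    whether it matches at +/-0.01.  Cells known not to reproduce from their
    own table are flagged, not failed.
    """
    ctrl = load_control_table()
    diab = load_diabetic_table()
    t1 = load_infarct_table()
    rows: list[dict] = []

    def add(table: str, cell: str, printed: float, computed: float, cmp_rule: str = "eq") -> None:
        if cmp_rule == "eq":
            ok = abs(computed - printed) <= RATIO_TOL
        else:  # "le": printed is an upper bound (significance level)
            ok = computed <= printed
        rows.append(
            {
                "table": table,
                "cell": cell,
                "printed": printed,
                "computed": computed,
                "cmp": cmp_rule,
                "match": ok,
                "flagged_inconsistent": (table, cell) in KNOWN_INCONSISTENT,
            }
        )

    for tname, df in (("table2", ctrl), ("table3", diab)):
        for _, r in df.iterrows():
            add(
                tname,
                f"ratio_rat{int(r['rat'])}",
                r["increased_ratio"],
                diffimg.ratio_from_sums(r["stress_rest_difference"], r["rest_activity"]),
            )
    for tname, df, prefix in (("table2", ctrl, "control"), ("table3", diab, "diabetic")):
        mean, se = ranktests.mean_se(df["increased_ratio"])
        add(tname, f"{prefix}_mean", PRINTED_SUMMARY[f"{prefix}_mean"], mean)
        add(tname, f"{prefix}_se", PRINTED_SUMMARY[f"{prefix}_se"], se)
    for col, prefix in (("fdg_pct", "fdg"), ("rbc_pct", "rbc"), ("ttc_pct", "ttc")):
        mean, se = ranktests.mean_se(t1[col])
        add("table1", f"{prefix}_mean", PRINTED_SUMMARY[f"{prefix}_mean"], mean)
        add("table1", f"{prefix}_se", PRINTED_SUMMARY[f"{prefix}_se"], se)

    rs = ranktests.rank_sum_exact(ctrl["increased_ratio"], diab["increased_ratio"])
    add("tables2v3", "rank_sum_U", 0.0, rs.statistic)
    add("tables2v3", "rank_sum_p", 0.05, rs.p_two_tailed, cmp_rule="le")
    for tname, df in (("table2", ctrl), ("table3", diab)):
        sr = ranktests.signed_rank_exact(
            df["stress_activity"].to_numpy(), df["rest_activity"].to_numpy()
        )
        add(tname, "signed_rank_W", 0.0, sr.statistic)
        add(tname, "signed_rank_p", 0.05, sr.p_two_tailed, cmp_rule="le")
    return pd.DataFrame(rows)
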