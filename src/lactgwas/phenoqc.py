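"""Trait derivation and edits for test-day records.

Works on pandas DataFrames with the phenotype schema::

    cow_id, herd, test_date, calving_date, birth_date, dim,
    my_kg, fp_pct, pp_pct, scc_kcells_per_ml, fy_kg, py_kg, scs

Somatic cell count (SCC) is in 1,000 cells/mL; the somatic cell score is
SCS = log2(SCC/100) + 3.  Fat and protein yields are derived from milk yield
and the component percentages: FY = FP*MY/100, PY = PP*MY/100.

Edits mirror common DHI practice for first-lactation test-day analyses:
record-level bounds on age at first calving, DIM and the trait values, then
cow-level requirements (record count, an early test, a calving-date cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: record-level inclusion bounds (inclusive except the strict SCC cap)
RECORD_BOUNDS = {
    "afc_months": (19, 37),
    "dim": (5, 305),
    "my_kg": (1.0, 65.0),
    "fp_pct": (0.5, 8.5),
    "pp_pct": (0.5, 7.5),
}
SCC_CAP_KCELLS = 2000.0  # < 2 million cells/mL, strict
MIN_RECORDS_PER_COW = 3
EARLY_TEST_DIM = 45  # at least one record before this DIM
DEFAULT_CALVING_CUTOFF = "2019-12-01"


@dataclass
class FilterReport:
    records_in: int = 0
    records_out: int = 0
    cows_in: int = 0
    cows_out: int = 0
    per_rule_rejections: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "records_in": self.records_in,
            "records_out": self.records_out,
            "cows_in": self.cows_in,
            "cows_out": self.cows_out,
            "per_rule_rejections": dict(self.per_rule_rejections),
        }


def compute_scs(scc):
    """Somatic cell score from SCC in 1,000 cells/mL: log2(scc/100) + 3."""
    scc = np.asarray(scc, dtype=float)
    if np.any(scc <= 0):
        raise ValueError("SCC must be positive for the log transform")
    out = np.log2(scc / 100.0) + 3.0
    return float(out) if out.ndim == 0 else out


def invert_scs(scs):
    """Inverse transform: SCC = 100 * 2**(scs - 3)."""
    scs = np.asarray(scs, dtype=float)
    out = 100.0 * np.exp2(scs - 3.0)
    return float(out) if out.ndim == 0 else out


def compute_component_yields(my, fp, pp):
    """(fat yield, protein yield) in kg/day from MY and the percentages."""
    my = np.asarray(my, dtype=float)
    if np.any(my < 0):
        raise ValueError("milk yield must be non-negative")
    fy = np.asarray(fp, dtype=float) * my / 100.0
    py = np.asarray(pp, dtype=float) * my / 100.0
    if fy.ndim == 0:
        return float(fy), float(py)
    return fy, py


def derive_traits(records: pd.DataFrame) -> pd.DataFrame:
    """Populate fy_kg, py_kg and scs from the raw columns (copy)."""
    out = records.copy()
    fy, py = compute_component_yields(
        out["my_kg"].to_numpy(), out["fp_pct"].to_numpy(), out["pp_pct"].to_numpy()
    )
    out["fy_kg"] = fy
    out["py_kg"] = py
    scc = out["scc_kcells_per_ml"].to_numpy(dtype=float)
    scs = np.full(len(out), np.nan)
    ok = scc > 0
    scs[ok] = np.log2(scc[ok] / 100.0) + 3.0
    out["scs"] = scs
    return out


def age_at_first_calving_months(birth_date, calving_date) -> np.ndarray:
    """Whole calendar months between birth and first calving (days ignored)."""
    b = pd.to_datetime(birth_date)
    c = pd.to_datetime(calving_date)
    return (c.dt.year - b.dt.year) * 12 + (c.dt.month - b.dt.month)


def apply_record_filters(records: pd.DataFrame):
    """Record-level edits; returns (kept records, FilterReport).

    Rules: age at first calving 19-37 months, DIM 5-305, MY 1.0-65 kg,
    FP 0.5-8.5 %, PP 0.5-7.5 %, SCC < 2000 (1,000 cells/mL).  Records with a
    missing required field are rejected under rule ``missing_field``.
    """
    df = records.copy()
    n = len(df)
    report = FilterReport(records_in=n, cows_in=df["cow_id"].nunique())
    required = [
        "cow_id", "birth_date", "calving_date", "dim",
        "my_kg", "fp_pct", "pp_pct", "scc_kcells_per_ml",
    ]
    missing = df[required].isna().any(axis=1)
    report.per_rule_rejections["missing_field"] = int(missing.sum())
    ok = ~missing

    afc = age_at_first_calving_months(df["birth_date"], df["calving_date"])
    rules = {
        "afc_range": afc.between(*RECORD_BOUNDS["afc_months"]),
        "dim_range": df["dim"].between(*RECORD_BOUNDS["dim"]),
        "my_range": df["my_kg"].between(*RECORD_BOUNDS["my_kg"]),
        "fp_range": df["fp_pct"].between(*RECORD_BOUNDS["fp_pct"]),
        "pp_range": df["pp_pct"].between(*RECORD_BOUNDS["pp_pct"]),
        "scc_cap": df["scc_kcells_per_ml"] < SCC_CAP_KCELLS,
    }
    for name, keep_mask in rules.items():
        keep_mask = keep_mask.fillna(False)
        report.per_rule_rejections[name] = int((~keep_mask & ~missing).sum())
        ok &= keep_mask
    kept = df[ok].copy()
    report.records_out = len(kept)
    report.cows_out = kept["cow_id"].nunique()
    return kept, report


def apply_cow_filters(records: pd.DataFrame, max_calving_date=DEFAULT_CALVING_CUTOFF):
    """Cow-level edits; returns (kept records, FilterReport).

    A cow is retained only with >= 3 surviving records, at least one record
    with DIM < 45, and a calving date strictly before ``max_calving_date``.
    """
    df = records.copy()
    cutoff = pd.Timestamp(max_calving_date)
    report = FilterReport(records_in=len(df), cows_in=df["cow_id"].nunique())
    grp = df.groupby("cow_id")
    n_rec = grp.size()
    has_early = grp["dim"].min() < EARLY_TEST_DIM
    calving_ok = pd.to_datetime(grp["calving_date"].first()) < cutoff

    bad_count = n_rec < MIN_RECORDS_PER_COW
    report.per_rule_rejections["min_records"] = int(bad_count.sum())
    report.per_rule_rejections["early_test"] = int((~has_early).sum())
    report.per_rule_rejections["calving_cutoff"] = int((~calving_ok).sum())

    keep_cows = n_rec.index[~bad_count & has_early & calving_ok]
    kept = df[df["cow_id"].isin(keep_cows)].copy()
    report.records_out = len(kept)
    report.cows_out = kept["cow_id"].nunique()
    return kept, report


def assign_factor_levels(
    records: pd.DataFrame, season_rule: str = "quarter", age_bin_months: int = 6
) -> pd.DataFrame:
    """Attach the fixed-effect class labels used by the test-day model.

    htd          herd x test-date cell
    age_class    calving month x age bin (age at first calving, binned)
    season_class calving year x season (default: calendar quarters)
    """
    df = records.copy()
    test_date = pd.to_datetime(df["test_date"])
    calving = pd.to_datetime(df["calving_date"])
    if test_date.isna().any() or calving.isna().any():
        raise ValueError("unparsable test_date or calving_date")
    df["htd"] = df["herd"].astype(str) + ":" + test_date.dt.strftime("%Y-%m-%d")
    afc = age_at_first_calving_months(df["birth_date"], df["calving_date"])
    age_bin = (afc // age_bin_months).astype(int)
    df["age_class"] = calving.dt.month.astype(str) + ":a" + age_bin.astype(str)
    if season_rule == "quarter":
        season = calving.dt.quarter
    elif season_rule == "half":
        season = (calving.dt.month > 6).astype(int) + 1
    else:
        raise ValueError(f"unknown season rule: {season_rule!r}")
    df["season_class"] = calving.dt.year.astype(str) + ":s" + season.astype(str)
    return df


TRAIT_COLUMNS = {
    "my_kg": "Milk yield (MY, kg/d)",
    "fy_kg": "Fat yield (FY, kg/d)",
    "py_kg": "Protein yield (PY, kg/d)",
    "fp_pct": "Fat (FP, %)",
    "pp_pct": "Protein (PP, %)",
    "scs": "SCS",
}


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV = SD / mean."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return sd / mean


def summarize_traits(records: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Descriptive statistics per trait: n records/animals, mean, SD, range, CV."""
    import warnings

    traits = traits or list(TRAIT_COLUMNS)
    rows = []
    for t in traits:
        vals = records[t].dropna()
        if len(vals) == 0:
            warnings.warn(f"no records for trait {t}; row omitted")
            continue
        mean = vals.mean()
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        rows.append(
            {
                "trait": t,
                "n_records": len(vals),
                "n_animals": records.loc[vals.index, "cow_id"].nunique(),
                "mean": mean,
                "sd": sd,
                "min": vals.min(),
                "max": vals.max(),
                "cv": sd / mean if mean != 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
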