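"""Repertoire summaries: segment usage, V-J pairing, CDR3 length and AA composition.

All statistics operate on a clonotype table (the pipeline's output format:
columns sample_id, v_call, j_call, cdr3, cdr3_aa, productive,
duplicate_count).  By default each unique clonotype counts once —
frequencies describe the diversity of distinct rearrangements rather than
their read abundance; pass ``weighting="abundance"`` to weight by
``duplicate_count`` instead (the natural choice when recovering configured
simulation frequencies).
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .germline import GermlineDatabase

#: default four-class amino-acid table.  The neutral-hydrophilic class
#: holds Ser/Thr/Asn/Gln/Tyr; cysteine is grouped with the hydrophobics.
#: The assignment is a documented convention and fully configurable.
DEFAULT_AA_CLASSES: Dict[str, str] = {
    **{aa: "hydrophobic" for aa in "AVLIPFMWGC"},
    **{aa: "neutral_hydrophilic" for aa in "STNQY"},
    **{aa: "acidic" for aa in "DE"},
    **{aa: "basic" for aa in "KRH"},
}

NORMAL_BAND = (4, 22)       # AA length band of typical CDR3γ
ULTRALONG_BAND = (23, 36)   # ultralong CDR3γ band


def _weights(clonotypes: pd.DataFrame, weighting: str) -> pd.Series:
    if weighting == "unique":
        return pd.Series(1.0, index=clonotypes.index)
    if weighting == "abundance":
        return clonotypes["duplicate_count"].astype(float)
    raise ValueError(f"unknown weighting {weighting!r}")


def segment_usage(
    clonotypes: pd.DataFrame,
    level: str = "V",
    db: Optional[GermlineDatabase] = None,
    weighting: str = "unique",
    per_sample: bool = False,
):
    """Frequency of each V or J segment (or V subgroup) in the repertoire.

    Frequencies sum to 1 (per sample when ``per_sample``).  The subgroup
    level requires the germline database for the V → subgroup mapping.
    """
    if clonotypes.empty:
        raise ValueError("empty clonotype table")
    if level == "V":
        key = clonotypes["v_call"]
    elif level == "J":
        key = clonotypes["j_call"]
    elif level == "subgroup":
        if db is None:
            raise ValueError("subgroup usage requires a germline database")
        key = clonotypes["v_call"].map(lambda v: db.subgroup_of(v) or "unassigned")
    else:
        raise ValueError(f"unknown level {level!r}")
    w = _weights(clonotypes, weighting)
    if per_sample:
        table = w.groupby([clonotypes["sample_id"], key]).sum().unstack(fill_value=0.0)
        return table.div(table.sum(axis=1), axis=0)
    totals = w.groupby(key).sum()
    return (totals / totals.sum()).sort_index()


def vj_pair_frequencies(
    clonotypes: pd.DataFrame,
    weighting: str = "unique",
) -> pd.DataFrame:
    """Empirical joint V×J frequency matrix (sums to 1).

    Row and column marginals equal the corresponding segment usage tables.
    """
    if clonotypes.empty:
        raise ValueError("empty clonotype table")
    w = _weights(clonotypes, weighting)
    table = w.groupby([clonotypes["v_call"], clonotypes["j_call"]]).sum().unstack(fill_value=0.0)
    return table / table.values.sum()


def cdr3_length_summary(
    clonotypes: pd.DataFrame,
    group_by: Optional[str] = None,
    db: Optional[GermlineDatabase] = None,
    sd_ddof: int = 1,
) -> pd.DataFrame:
    """CDR3 nucleotide-length summaries over productive clonotypes.

    Returns one row per group (or a single "all" row) with n, mean, sd
    (sample SD by default), median, quartiles and the mean AA length
    (= mean nt / 3, exact because productive lengths are multiples of 3).
    """
    prod = clonotypes[clonotypes["productive"]]
    if prod.empty:
        raise ValueError("no productive clonotypes")
    lengths = prod["cdr3"].str.len().astype(float)
    if group_by is None:
        groups = pd.Series("all", index=prod.index)
    elif group_by == "V":
        groups = prod["v_call"]
    elif group_by == "J":
        groups = prod["j_call"]
    elif group_by == "subgroup":
        if db is None:
            raise ValueError("subgroup grouping requires a germline database")
        groups = prod["v_call"].map(lambda v: db.subgroup_of(v) or "unassigned")
    else:
        raise ValueError(f"unknown group_by {group_by!r}")
    rows = []
    for name, vals in lengths.groupby(groups):
        arr = vals.to_numpy()
        rows.append({
            "group": name, "n": arr.size,
            "mean_nt": float(arr.mean()),
            "sd_nt": float(arr.std(ddof=sd_ddof)) if arr.size > sd_ddof else 0.0,
            "median_nt": float(np.median(arr)),
            "q1_nt": float(np.percentile(arr, 25)),
            "q3_nt": float(np.percentile(arr, 75)),
            "mean_aa": float(arr.mean()) / 3.0,
        })
    return pd.DataFrame(rows).set_index("group")


def cdr3_length_histogram(clonotypes: pd.DataFrame, unit: str = "nt") -> pd.Series:
    """Histogram of productive CDR3 lengths in nt or AA."""
    prod = clonotypes[clonotypes["productive"]]
    lengths = prod["cdr3"].str.len()
    if unit == "aa":
        lengths = lengths // 3
    elif unit != "nt":
        raise ValueError("unit must be 'nt' or 'aa'")
    return lengths.value_counts().sort_index()


def aa_composition(
    clonotypes: pd.DataFrame,
    class_table: Mapping[str, str] = DEFAULT_AA_CLASSES,
    normal_band: Tuple[int, int] = NORMAL_BAND,
    ultralong_band: Tuple[int, int] = ULTRALONG_BAND,
) -> Tuple[pd.DataFrame, pd.DataFrame, int]:
    """Per-amino-acid and per-class composition of normal vs ultralong CDR3γ.

    Residues are pooled over productive CDR3 peptides within each AA-length
    band.  Returns (per-AA frequencies with bands as columns, per-class
    frequencies, count of clonotypes outside both bands).
    """
    missing = set("ACDEFGHIKLMNPQRSTVWY") - set(class_table)
    if missing:
        raise ValueError(f"class table misses amino acids: {sorted(missing)}")
    prod = clonotypes[clonotypes["productive"]]
    bands = {"normal": normal_band, "ultralong": ultralong_band}
    counts = {band: pd.Series(0, index=sorted(set(class_table)), dtype=float)
              for band in bands}
    other = 0
    for aa_seq in prod["cdr3_aa"]:
        n = len(aa_seq)
        for band, (lo, hi) in bands.items():
            if lo <= n <= hi:
                for ch in aa_seq:
                    counts[band][ch] += 1
                break
        else:
            other += 1
    per_aa = pd.DataFrame(counts)
    totals = per_aa.sum()
    per_aa = per_aa.div(totals.where(totals > 0, 1.0))
    per_class = per_aa.groupby(pd.Series(class_table)).sum()
    return per_aa, per_class, other


def retention_report(stage_counts: pd.DataFrame) -> Tuple[pd.DataFrame, float, float]:
    """Filter-retention arithmetic per sample, with the min–max range.

    Input columns: sample_id, unique_vregion, pseudo_orf_dropped,
    productive.  ``post_filter = unique − dropped`` and
    ``productive_pct = 100 × productive / post_filter``.
    """
    required = {"sample_id", "unique_vregion", "pseudo_orf_dropped", "productive"}
    missing = required - set(stage_counts.columns)
    if missing:
        raise ValueError(f"stage counts missing columns: {sorted(missing)}")
    df = stage_counts.copy()
    if (df["pseudo_orf_dropped"] > df["unique_vregion"]).any():
        raise ValueError("dropped count exceeds unique V-region count")
    df["post_filter"] = df["unique_vregion"] - df["pseudo_orf_dropped"]
    if (df["productive"] > df["post_filter"]).any():
        raise ValueError("productive count exceeds post-filter count")
    df["productive_pct"] = 100.0 * df["productive"] / df["post_filter"]
    return df, float(df["productive_pct"].min()), float(df["productive_pct"].max())
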