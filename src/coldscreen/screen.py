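"""Screen statistics: CK1 filtering, abundance ratios, hit calling,
two-group classification and gene-level aggregation.

Samples: CK1 is the initial mutant pool, CK2 the room-temperature control
after serial dilution, S10 the pool after four days at 10 °C, and S10R the
post-cold recovery pool.  For each barcode, relative abundance is its
count divided by the sample's recognized-read total; the screening
statistic is the ratio of ratios

    rr = (S10/CK1 + offset) / (CK2/CK1 + offset)

with offset 0.001 (the same offset used for log2 reporting), hit
thresholds rr > 3 (enriched) or rr < 0.3 (depleted), both strict, applied
to barcodes with CK1 count >= 50.  Hits split into two groups: group 1 is
defective at normal temperature but relatively rescued in cold (enriched,
log2(CK2/CK1 + offset) below a cut, default -1); group 2 grows normally
at room temperature but is inhibited specifically in cold (depleted, at
or above the cut).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from coldscreen.barcodes import CountMatrix

CK1, CK2, S10, S10R = "CK1", "CK2", "S10", "S10R"


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the ratio screen; defaults are the published rule
    (CK1 >= 50, rr > 3 or < 0.3, offset 0.001) except ``group_split_log2``,
    which is this package's configurable cut for the two-group split."""

    min_ck1_count: int = 50
    up_threshold: float = 3.0
    down_threshold: float = 0.3
    offset: float = 0.001
    group_split_log2: float = -1.0

    def __post_init__(self) -> None:
        if not (self.down_threshold < 1.0 < self.up_threshold):
            raise ValueError("need down_threshold < 1 < up_threshold")
        if self.offset <= 0:
            raise ValueError("offset must be > 0")
        if self.min_ck1_count < 1:
            raise ValueError("min_ck1_count must be >= 1")

    def as_dict(self) -> dict:
        return asdict(self)


def filter_min_ck1(matrix: CountMatrix, config: ScreenConfig) -> tuple[set[str], dict]:
    """Barcodes with CK1 read count >= ``min_ck1_count`` (inclusive)."""
    if CK1 not in matrix.samples:
        raise ValueError(f"count matrix has no {CK1} column (samples: {matrix.samples})")
    ck1 = matrix.df[CK1]
    retained = set(ck1.index[ck1 >= config.min_ck1_count])
    report = {
        "n_barcodes": len(ck1),
        "retained": len(retained),
        "dropped": len(ck1) - len(retained),
        "min_ck1_count": config.min_ck1_count,
    }
    return retained, report


def classify_rr(
    r_ctrl: np.ndarray, r_cold: np.ndarray, config: ScreenConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised hit/direction/group rule on CK2/CK1 and S10/CK1 ratios.

    Returns ``(rr, hit, direction, group)``.  This single function is the
    classification rule: the simulator's expected-group truth and the
    pipeline both call it.
    """
    r_ctrl = np.asarray(r_ctrl, dtype=float)
    r_cold = np.asarray(r_cold, dtype=float)
    rr = (r_cold + config.offset) / (r_ctrl + config.offset)
    enriched = rr > config.up_threshold
    depleted = rr < config.down_threshold
    hit = enriched | depleted
    direction = np.where(enriched, "enriched", np.where(depleted, "depleted", "none"))
    log2_ctrl = np.log2(r_ctrl + config.offset)
    group = np.full(rr.shape, "none", dtype=object)
    group[(log2_ctrl < config.group_split_log2) & enriched] = "group1"
    group[(log2_ctrl >= config.group_split_log2) & depleted] = "group2"
    return rr, hit, direction.astype(object), group


def compute_ratios(
    matrix: CountMatrix, retained: Iterable[str], config: ScreenConfig
) -> pd.DataFrame:
    """Per-barcode screen records for the retained barcodes.

    Relative abundance divides each count by its sample's recognized-read
    total (whole-matrix column sum, not the retained subset).  Requires
    CK1, CK2 and S10; S10R ratios are reported when present but play no
    part in hit calling.
    """
    needed = [CK1, CK2, S10]
    missing = [s for s in needed if s not in matrix.samples]
    if missing:
        raise ValueError(f"count matrix lacks required samples: {missing}")
    totals = matrix.totals
    zero = [s for s in matrix.samples if totals[s] == 0]
    if zero:
        raise ValueError(f"samples with zero recognized reads: {zero}")

    retained = sorted(set(retained))
    unknown = set(retained) - set(matrix.barcodes)
    if unknown:
        raise ValueError(f"retained barcodes absent from matrix: {sorted(unknown)[:5]}")
    sub = matrix.df.loc[retained]
    out = pd.DataFrame(index=pd.Index(retained, name="barcode"))
    have_rec = S10R in matrix.samples
    for s in needed + ([S10R] if have_rec else []):
        out[f"count_{s}"] = sub[s]
        out[f"rel_{s}"] = sub[s] / totals[s]
    out["r_ctrl"] = out[f"rel_{CK2}"] / out[f"rel_{CK1}"]
    out["r_cold"] = out[f"rel_{S10}"] / out[f"rel_{CK1}"]
    if have_rec:
        out["r_rec"] = out[f"rel_{S10R}"] / out[f"rel_{CK1}"]
    return out


def call_hits(records: pd.DataFrame, config: ScreenConfig) -> pd.DataFrame:
    """Add rr, hit and direction columns (strict > / < thresholds)."""
    records = records.copy()
    rr, hit, direction, _ = classify_rr(records["r_ctrl"], records["r_cold"], config)
    records["rr"] = rr
    records["hit"] = hit
    records["direction"] = direction
    return records


def assign_group(records: pd.DataFrame, config: ScreenConfig) -> pd.DataFrame:
    """Add the two-group classification for hit barcodes."""
    records = records.copy()
    _, _, _, group = classify_rr(records["r_ctrl"], records["r_cold"], config)
    records["group"] = group
    return records


def screen_barcodes(matrix: CountMatrix, config: ScreenConfig) -> tuple[pd.DataFrame, dict]:
    """Filter, compute ratios, call hits and groups in one pass."""
    retained, filter_report = filter_min_ck1(matrix, config)
    records = compute_ratios(matrix, retained, config)
    records = assign_group(call_hits(records, config), config)
    summary = {
        "filter": filter_report,
        "n_hits": int(records["hit"].sum()),
        "n_enriched": int((records["direction"] == "enriched").sum()),
        "n_depleted": int((records["direction"] == "depleted").sum()),
        "n_group1": int((records["group"] == "group1").sum()),
        "n_group2": int((records["group"] == "group2").sum()),
        "n_ungrouped_hits": int(
            (records["hit"] & (records["group"] == "none")).sum()
        ),
        "config": config.as_dict(),
        # conventions that published threshold rules leave open
        "conventions": {
            "ratios": "relative_abundance",
            "offset_applied_in_rr": True,
        },
    }
    return records, summary


def aggregate_by_gene(
    records: pd.DataFrame,
    annot: pd.DataFrame,
    early_cold_list: set[str] | Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Aggregate hit barcodes to candidate genes.

    ``annot`` is the insertion-annotation table (columns ``barcode``,
    ``gene_id``, ``category``, optionally ``status``).  Only hit barcodes
    with a unique-status, non-intergenic annotation support a gene.  The
    dominant group is the majority over supporting barcodes; a tie goes
    to group 2 and is flagged.  ``in_early_cold_list`` is an exact
    string-match membership test.
    """
    early = set(early_cold_list or ())
    ann = annot.copy()
    if "status" in ann.columns:
        ann = ann[ann["status"] == "unique"]
    ann = ann[(ann["category"] != "intergenic") & (ann["gene_id"].astype(str) != "")]
    ann = ann.drop_duplicates(subset="barcode").set_index("barcode")

    hits = records[records["hit"]]
    mapped_hits = hits.join(ann[["gene_id", "category"]], how="inner")

    rows = []
    for gene_id, grp in sorted(mapped_hits.groupby("gene_id")):
        n1 = int((grp["group"] == "group1").sum())
        n2 = int((grp["group"] == "group2").sum())
        if n1 == n2 == 0:
            dominant, tie = "none", False
        elif n1 == n2:
            dominant, tie = "group2", True
        else:
            dominant, tie = ("group1" if n1 > n2 else "group2"), False
        rows.append(
            {
                "gene_id": gene_id,
                "n_barcodes": len(grp),
                "barcodes": ",".join(sorted(grp.index)),
                "n_group1": n1,
                "n_group2": n2,
                "dominant_group": dominant,
                "group_tie": tie,
                "categories": ",".join(sorted(set(grp["category"]))),
                "in_early_cold_list": gene_id in early,
            }
        )
    cols = [
        "gene_id", "n_barcodes", "barcodes", "n_group1", "n_group2",
        "dominant_group", "group_tie", "categories", "in_early_cold_list",
    ]
    genes = pd.DataFrame(rows, columns=cols)
    summary = {
        "n_hit_barcodes": int(records["hit"].sum()),
        "n_mapped_hit_barcodes": len(mapped_hits),
        "n_candidate_genes": len(genes),
        "n_early_cold_overlap": int(genes["in_early_cold_list"].sum()) if len(genes) else 0,
    }
    return genes, summary


def scatter_table(records: pd.DataFrame, config: ScreenConfig) -> pd.DataFrame:
    """Per-barcode plotting table: log2(CK2/CK1 + offset) on x,
    log2(S10/CK1 + offset) on y, with hit/group flags."""
    out = pd.DataFrame(index=records.index)
    out["log2_r_ctrl"] = np.log2(records["r_ctrl"] + config.offset)
    out["log2_r_cold"] = np.log2(records["r_cold"] + config.offset)
    out["hit"] = records["hit"]
    out["direction"] = records["direction"]
    out["group"] = records["group"]
    out["highlight"] = records["group"] != "none"
    return out


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t")
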