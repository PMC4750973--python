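"""Fold-change categorization of a two-condition expression table.

Fold change is the linear absolute ratio max(a/b, b/a); the direction is
given by which condition is higher. Only records flagged significant are
categorized. A gene expressed in one condition and at (or below) the
detection floor in the other is "exclusive" rather than given an infinite
ratio. The primary gate is >= fold_threshold; the strong subset uses a
strict > strong_threshold.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .models import DESummary

CATEGORIES = (
    "shared_down",
    "shared_up",
    "only_control",
    "only_kd",
    "unchanged",
)

REQUIRED_COLUMNS = ("gene_id", "expr_control", "expr_kd", "significant")


def categorize_de(
    records: pd.DataFrame,
    fold_threshold: float = 1.5,
    strong_threshold: float = 2.0,
    floor: float = 0.0,
) -> tuple[DESummary, pd.DataFrame]:
    """Categorize every gene and tally the summary counts.

    Returns (summary, per-gene table with added 'category', 'fold_change'
    and 'strong' columns). ``floor`` is the detection cutoff below which a
    gene counts as not expressed (default exactly 0).
    """
    if fold_threshold <= 1 or strong_threshold <= 1:
        raise ValueError("thresholds must be > 1")
    if floor < 0:
        raise ValueError("floor must be >= 0")
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"missing column {col!r}")
    if (records["expr_control"] < 0).any() or (records["expr_kd"] < 0).any():
        raise ValueError("negative expression values")

    cats, folds, strongs = [], [], []
    s = DESummary()
    for r in records.itertuples():
        ctrl, kd, sig = float(r.expr_control), float(r.expr_kd), bool(r.significant)
        ctrl_on, kd_on = ctrl > floor, kd > floor
        if ctrl_on and kd_on:
            fold = max(ctrl / kd, kd / ctrl)
        else:
            fold = float("inf") if (ctrl_on or kd_on) else 1.0
        strong = False
        if not sig:
            cat = "unchanged"
        elif ctrl_on and not kd_on:
            cat = "only_control"
            s.n_only_control += 1
        elif kd_on and not ctrl_on:
            cat = "only_kd"
            s.n_only_kd += 1
        elif not ctrl_on and not kd_on:
            cat = "unchanged"
        elif fold >= fold_threshold:
            if ctrl > kd:
                cat = "shared_down"
                s.n_shared_down += 1
                strong = fold > strong_threshold
                s.n_shared_down_strong += int(strong)
            else:
                cat = "shared_up"
                s.n_shared_up += 1
                strong = fold > strong_threshold
                s.n_shared_up_strong += int(strong)
        else:
            cat = "unchanged"
        cats.append(cat)
        folds.append(fold)
        strongs.append(strong)
    out = records.copy()
    out["category"] = cats
    out["fold_change"] = folds
    out["strong"] = strongs
    return s, out


def write_de_report(
    summary: DESummary, per_gene: pd.DataFrame, tsv_path, json_path=None
) -> None:
    per_gene.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(summary.as_dict(), indent=2) + "\n")


def read_de_report(json_path) -> DESummary:
    d = json.loads(Path(json_path).read_text())
    return DESummary(
        n_shared_down=d["n_shared_down"],
        n_shared_up=d["n_shared_up"],
        n_only_control=d["n_only_control"],
        n_only_kd=d["n_only_kd"],
        n_shared_down_strong=d["n_shared_down_strong"],
        n_shared_up_strong=d["n_shared_up_strong"],
    )


def read_de_table(path) -> pd.DataFrame:
    """TSV with header gene_id, expr_control, expr_kd, significant[, q_value]."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {missing}")
    if df["significant"].dtype == object:
        df["significant"] = df["significant"].map(
            lambda v: str(v).strip().lower() in {"1", "true", "yes"}
        )
    return df
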