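"""Effect categories and deleteriousness.

Variants are binned into the screen's effect categories using externally
supplied substitution-tolerance scores (SIFT-like, in [0, 1], lower = more
damaging; threshold 0.05).  Scores are an input channel only — they are
never computed here.  A missense variant with no score is reported as
`unscored_missense` rather than silently tolerated, so missing annotations
cannot masquerade as benign.

The boundary case score == 0.05: the screen defines deleterious as < 0.05
and tolerated as > 0.05, leaving 0.05 unassigned; the strict reading is
used, so exactly 0.05 is tolerated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .consequence import ConsequenceRecord
from .errors import ValidationError

CATEGORIES = [
    "same_sense",
    "tolerated_missense",
    "deleterious_missense",
    "nonsense",
    "frameshift",
    "splice_disrupting",
    "splice_region",
    "other_noncoding",
    "unscored_missense",
]

DELETERIOUS_CATEGORIES = {
    "deleterious_missense",
    "nonsense",
    "frameshift",
    "splice_disrupting",
}

SIFT_THRESHOLD = 0.05


@dataclass(frozen=True)
class ScoreRecord:
    variant_key: str
    score: float
    source: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(
                f"score {self.score} for {self.variant_key} outside [0, 1]"
            )


def read_scores(path: str | Path) -> dict[str, ScoreRecord]:
    """Read a scores TSV (columns: variant_id, score[, source])."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    if "variant_id" not in df.columns or "score" not in df.columns:
        raise ValidationError(f"{path}: scores TSV needs variant_id and score columns")
    out = {}
    for row in df.itertuples(index=False):
        src = getattr(row, "source", "") or ""
        out[row.variant_id] = ScoreRecord(row.variant_id, float(row.score), str(src))
    return out


def classify_effect(
    c: ConsequenceRecord,
    s: Optional[ScoreRecord] = None,
    threshold: float = SIFT_THRESHOLD,
    splice_region_deleterious: bool = False,
) -> str:
    """Assign the effect category for one (variant, gene) consequence."""
    if not 0.0 < threshold < 1.0:
        raise ValidationError(f"threshold {threshold} outside (0, 1)")
    if s is not None and not 0.0 <= s.score <= 1.0:
        raise ValidationError(f"score {s.score} outside [0, 1]")
    label = c.label
    if label == "synonymous":
        return "same_sense"
    if label == "missense":
        if s is None:
            return "unscored_missense"
        return "deleterious_missense" if s.score < threshold else "tolerated_missense"
    if label == "nonsense":
        return "nonsense"
    if label == "frameshift":
        return "frameshift"
    if label in {"splice_donor", "splice_acceptor", "splice_disrupting"}:
        return "splice_disrupting"
    if label == "splice_region":
        return "splice_disrupting" if splice_region_deleterious else "splice_region"
    if label in {"start_loss", "stop_loss"}:
        # loss of the start or stop codon removes/extends the protein; treated
        # with the high-impact (nonsense-like) class
        return "nonsense"
    if label in {"inframe_del", "inframe_ins", "inframe_dup", "inframe_delins"}:
        # in-frame events are scored like missense when a score is available
        if s is None:
            return "unscored_missense"
        return "deleterious_missense" if s.score < threshold else "tolerated_missense"
    return "other_noncoding"


def is_deleterious(category: str) -> bool:
    """True for the categories counted as deleterious by the screen."""
    if category not in CATEGORIES:
        raise ValidationError(f"unknown effect category {category!r}")
    return category in DELETERIOUS_CATEGORIES


def effect_counts(
    consequences: Iterable[ConsequenceRecord],
    scores: Mapping[str, ScoreRecord],
    threshold: float = SIFT_THRESHOLD,
    splice_region_deleterious: bool = False,
) -> pd.DataFrame:
    """Per-locus counts by effect category and variant class (SNP vs InDel).

    The counts partition the input: every (variant, gene) pair lands in
    exactly one (locus, category, class) cell.
    """
    rows = []
    for c in consequences:
        cat = classify_effect(
            c, scores.get(c.variant_key), threshold, splice_region_deleterious
        )
        rows.append(
            {
                "gene_id": c.gene_id,
                "category": cat,
                "variant_class": "SNP" if c.is_snp else "InDel",
            }
        )
    if not rows:
        return pd.DataFrame(columns=["gene_id", "category", "variant_class", "count"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["gene_id", "category", "variant_class"], sort=True)
        .size()
        .reset_index(name="count")
    )
    return out
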