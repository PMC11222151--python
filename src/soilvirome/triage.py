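"""Selection of non-integrated virus genomes from classifier output.

Each assembled contig arrives with an upstream virus-classifier assessment
(virus score in [0,1], count of viral hallmark genes such as terminase or
capsid, a real-valued virus-marker enrichment statistic, a completeness
quality tier, and provirus flags). Contigs are accepted as virus genomes by
one of three rules, after discarding proviruses and contigs under 1 kb:

rule 1  completeness tier in {complete, high, medium} OR a direct terminal
        repeat (DTR) of >= 20 bp;
rule 2  length > 10 kb, virus score > 0.8, and (>= 1 hallmark gene OR
        marker enrichment >= 5.0);
rule 3  5 kb < length <= 10 kb, virus score > 0.9, >= 1 hallmark gene AND
        marker enrichment > 2.0.

Length boundaries are strict as written: a 10 kb contig falls under rule 3,
a 5 kb contig can only be accepted via rule 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ViralAssessment",
    "TriageConfig",
    "TriageDecision",
    "assessments_from_frame",
    "detect_dtr",
    "classify_contig",
    "triage_set",
]

QUALITY_TIERS = ("complete", "high", "medium", "low", "not-determined")
_RULE1_TIERS = frozenset({"complete", "high", "medium"})


@dataclass
class ViralAssessment:
    contig_id: str
    length: int
    virus_score: float = 0.0
    n_hallmarks: int = 0
    marker_enrichment: float = 0.0
    checkv_quality: str = "not-determined"
    provirus_flag: bool = False
    has_dtr: bool = False

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("length must be >= 0")
        if not 0.0 <= self.virus_score <= 1.0:
            raise ValueError("virus_score must lie in [0, 1]")
        if self.checkv_quality not in QUALITY_TIERS:
            raise ValueError(f"unknown quality tier {self.checkv_quality!r}")


@dataclass
class TriageConfig:
    min_len: int = 1_000
    long_len: int = 10_000
    mid_len: int = 5_000
    long_score: float = 0.8
    long_enrichment: float = 5.0
    mid_score: float = 0.9
    mid_enrichment: float = 2.0
    dtr_min_len: int = 20

    def __post_init__(self) -> None:
        if not self.min_len <= self.mid_len <= self.long_len:
            raise ValueError("require min_len <= mid_len <= long_len")


@dataclass
class TriageDecision:
    contig_id: str
    accepted: bool
    rule: str  # rule1_checkv_or_dtr | rule2_long | rule3_mid |
    #            rejected_provirus | rejected_short | rejected_no_rule


def assessments_from_frame(df: pd.DataFrame) -> list[ViralAssessment]:
    """Build assessments from a TSV-derived frame (one row per contig)."""
    out = []
    for r in df.to_dict("records"):
        out.append(
            ViralAssessment(
                contig_id=str(r["contig_id"]),
                length=int(r["length"]),
                virus_score=float(r.get("virus_score", 0.0)),
                n_hallmarks=int(r.get("n_hallmarks", 0)),
                marker_enrichment=float(r.get("marker_enrichment", 0.0)),
                checkv_quality=str(r.get("checkv_quality", "not-determined")),
                provirus_flag=bool(r.get("provirus_flag", False)),
                has_dtr=bool(r.get("has_dtr", False)),
            )
        )
    return out


def detect_dtr(sequence: str, dtr_min_len: int = 20) -> bool:
    """True iff a non-overlapping exact prefix recurs as a suffix at length
    >= ``dtr_min_len``."""
    n = len(sequence)
    if n < 2 * dtr_min_len:
        logger.warning("sequence of %d bp too short for DTR >= %d bp", n, dtr_min_len)
        return False
    for k in range(n // 2, dtr_min_len - 1, -1):
        if sequence[:k] == sequence[-k:]:
            return True
    return False


def classify_contig(a: ViralAssessment, cfg: TriageConfig | None = None) -> TriageDecision:
    cfg = cfg or TriageConfig()
    if a.provirus_flag:
        return TriageDecision(a.contig_id, False, "rejected_provirus")
    if a.length < cfg.min_len:
        return TriageDecision(a.contig_id, False, "rejected_short")
    if a.checkv_quality in _RULE1_TIERS or a.has_dtr:
        return TriageDecision(a.contig_id, True, "rule1_checkv_or_dtr")
    if a.length > cfg.long_len:
        if a.virus_score > cfg.long_score and (
            a.n_hallmarks >= 1 or a.marker_enrichment >= cfg.long_enrichment
        ):
            return TriageDecision(a.contig_id, True, "rule2_long")
    elif a.length > cfg.mid_len:
        if (
            a.virus_score > cfg.mid_score
            and a.n_hallmarks >= 1
            and a.marker_enrichment > cfg.mid_enrichment
        ):
            return TriageDecision(a.contig_id, True, "rule3_mid")
    return TriageDecision(a.contig_id, False, "rejected_no_rule")


def triage_set(
    assessments: list[ViralAssessment],
    cfg: TriageConfig | None = None,
    sequences: dict[str, str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Classify every contig; returns (accepted ids, decision table).

    If ``sequences`` is given, DTRs are recomputed from the sequences and
    OR-ed into each assessment's ``has_dtr`` before classification.
    Duplicate contig ids raise ``ValueError``.
    """
    cfg = cfg or TriageConfig()
    ids = [a.contig_id for a in assessments]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate contig ids in assessment set")
    decisions = []
    for a in assessments:
        if sequences is not None and a.contig_id in sequences and not a.has_dtr:
            a.has_dtr = detect_dtr(sequences[a.contig_id], cfg.dtr_min_len)
        decisions.append(classify_contig(a, cfg))
    table = pd.DataFrame(
        {
            "contig_id": [d.contig_id for d in decisions],
            "accepted": [d.accepted for d in decisions],
            "rule": [d.rule for d in decisions],
        }
    )
    accepted = table.loc[table["accepted"], "contig_id"].tolist()
    if not table.empty:
        counts = table["rule"].value_counts()
        logger.info("triage summary: %s", counts.to_dict())
    return accepted, table
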