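"""External formats and sample curation.

Readers/writers for FASTA, header-bearing TSV and the 12-column tabular
alignment dialect (query, subject, %identity, alignment length, mismatches,
gap opens, qstart, qend, sstart, send, e-value, bitscore; 1-based inclusive
coordinates, subject coordinates reversed on the minus strand), plus the
metadata exclusion filters used to restrict a metagenome collection to
genuine soil samples.

External coordinates are 1-based inclusive; everything internal is 0-based
half-open, converted only at this boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CurationRules",
    "curate_samples",
    "read_fasta",
    "write_fasta",
    "read_tsv",
    "write_tsv",
    "read_alignments",
    "write_alignments",
    "ALIGNMENT_COLUMNS",
]

ALIGNMENT_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

# Default exclusion lists: GOLD-style ecosystem types/subtypes, title phrases,
# geographic locations and project types that indicate a non-soil or
# manipulated sample.
_EXCLUDED_TYPES = {
    "rock-dwelling",
    "deep subsurface",
    "plant litter",
    "geologic",
    "oil reservoir",
    "volcanic",
    "contaminated",
}
_EXCLUDED_SUBTYPES = {
    "wetlands",
    "aquifer",
    "tar",
    "sediment",
    "fracking water",
    "soil crust",
}
_EXCLUDED_TITLE_WORDS = {
    "wetland",
    "sediment",
    "acid mine",
    "cave wall surface",
    "mine tailings",
    "rock biofilm",
    "beach sand",
    "petroleum",
    "stalagmite",
    "subsurface hydrocarbon microbial communities",
    "vadose zone",
    "mud volcano",
    "fumarolic",
    "enriched",
    "composted filter cake",
    "ice psychrophilic",
    "oil sands",
    "groundwater",
    "contaminated",
    "deep mine",
    "coal mine fire",
    "hydrocarbon resource environments",
    "marine",
    "enrichment",
    "mangrove",
    "saline desert",
    "hydroxyproline",
    "rifle",
    "coastal",
    "compost",
    "biocrust",
    "crust",
    "creosote",
    "soil warming",
    "testing DNA extraction",
    "agave",
}
_EXCLUDED_LOCATIONS = {"wetland"}
_EXCLUDED_PROJECT_TYPES = {"Metagenome - Cell Enrichment"}


@dataclass
class CurationRules:
    """Field-wise exclusion sets for sample curation.

    Title matching is word-boundary, case-insensitive phrase matching (so
    "crust" does not fire inside "biocrust"; both phrases are listed
    explicitly). All other fields match case-insensitively on the whole
    value.
    """

    excluded_ecosystem_types: set[str] = field(default_factory=lambda: set(_EXCLUDED_TYPES))
    excluded_ecosystem_subtypes: set[str] = field(default_factory=lambda: set(_EXCLUDED_SUBTYPES))
    excluded_title_words: set[str] = field(default_factory=lambda: set(_EXCLUDED_TITLE_WORDS))
    excluded_locations: set[str] = field(default_factory=lambda: set(_EXCLUDED_LOCATIONS))
    excluded_project_types: set[str] = field(default_factory=lambda: set(_EXCLUDED_PROJECT_TYPES))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CurationRules":
        """Load rule overrides from a YAML mapping of field name -> list."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown curation rule fields: {sorted(unknown)}")
        return cls(**{k: set(v) for k, v in data.items()})


def _title_pattern(words: set[str]) -> re.Pattern | None:
    if not words:
        return None
    # longest phrase first so the reported reason is the most specific match
    alts = sorted((re.escape(w) for w in words), key=len, reverse=True)
    return re.compile(r"\b(" + "|".join(alts) + r")\b", re.IGNORECASE)


#: plausible ranges for optional soil covariates (units: kg dm-3, cmol_c kg-1,
#: g kg-1, pH, g kg-1, %); values outside warn but never error
COVARIATE_RANGES = {
    "bulk_density": (0.24, 1.56),
    "cec": (6.8, 71.0),
    "nitrogen": (0.19, 22.4),
    "ph": (4.3, 8.5),
    "soc": (1.9, 510.9),
    "clay": (2.7, 57.1),
}


def validate_covariates(samples: pd.DataFrame) -> list[str]:
    """Warn (and return messages) for covariates outside plausible soil
    ranges; out-of-range values are flagged, never rejected."""
    messages = []
    for col, (lo, hi) in COVARIATE_RANGES.items():
        if col not in samples.columns:
            continue
        vals = pd.to_numeric(samples[col], errors="coerce")
        bad = samples.loc[(vals < lo) | (vals > hi), "sample_id"]
        for sid in bad:
            msg = f"sample {sid}: {col} outside plausible range [{lo}, {hi}]"
            logger.warning(msg)
            messages.append(msg)
    return messages


def curate_samples(
    samples: pd.DataFrame, rules: CurationRules | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a sample-metadata table into (kept, excluded-with-reason).

    A sample is excluded iff any metadata field matches its rule set; the
    first matching rule (in field order: ecosystem type, subtype, title,
    location, project type) is recorded as ``exclusion_reason``. Missing
    fields never match (they are logged). Curation is idempotent: re-curating
    the kept set excludes nothing.
    """
    rules = rules or CurationRules()
    pattern = _title_pattern(rules.excluded_title_words)
    lowered = {
        "ecosystem_type": {v.lower() for v in rules.excluded_ecosystem_types},
        "ecosystem_subtype": {v.lower() for v in rules.excluded_ecosystem_subtypes},
        "geographic_location": {v.lower() for v in rules.excluded_locations},
        "project_type": {v.lower() for v in rules.excluded_project_types},
    }
    reason_name = {
        "ecosystem_type": "ecosystem_type",
        "ecosystem_subtype": "ecosystem_subtype",
        "geographic_location": "location",
        "project_type": "project_type",
    }

    reasons: list[str | None] = []
    for _, row in samples.iterrows():
        reason = None
        for col in ("ecosystem_type", "ecosystem_subtype"):
            val = row.get(col)
            if pd.isna(val) if not isinstance(val, str) else False:
                logger.info("sample %s missing %s", row.get("sample_id"), col)
            elif isinstance(val, str) and val.lower() in lowered[col]:
                reason = f"{reason_name[col]}: {val}"
                break
        if reason is None and pattern is not None:
            title = row.get("title")
            if isinstance(title, str):
                m = pattern.search(title)
                if m:
                    reason = f"title word: {m.group(1).lower()}"
        if reason is None:
            for col in ("geographic_location", "project_type"):
                val = row.get(col)
                if isinstance(val, str) and val.lower() in lowered[col]:
                    reason = f"{reason_name[col]}: {val}"
                    break
        reasons.append(reason)

    mask = pd.Series(reasons, index=samples.index)
    kept = samples[mask.isna()].copy()
    excluded = samples[mask.notna()].copy()
    excluded["exclusion_reason"] = mask[mask.notna()]
    return kept, excluded


# ---------------------------------------------------------------------------
# format I/O


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_alignments(path: str | Path) -> pd.DataFrame:
    """Read a 12-column tabular alignment file, validating every row.

    Raises ``ValueError`` naming the (1-based) line number of any row with
    the wrong column count or unparsable numeric fields. ``sstart > send``
    encodes a minus-strand subject alignment.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(parts)}"
                )
            try:
                rows.append(
                    (
                        parts[0],
                        parts[1],
                        float(parts[2]),
                        int(parts[3]),
                        int(parts[4]),
                        int(parts[5]),
                        int(parts[6]),
                        int(parts[7]),
                        int(parts[8]),
                        int(parts[9]),
                        float(parts[10]),
                        float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def write_alignments(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=ALIGNMENT_COLUMNS)
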