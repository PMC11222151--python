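"""Pairwise alignment records and ANI/AF, AAI/shared-gene reductions.

The atlas-scale pipeline consumes all-vs-all nucleotide and protein
alignments produced externally; here those tables are reduced to per-pair
statistics:

* ANI — length-weighted mean of per-alignment identities, weights being the
  raw (unmerged) alignment lengths;
* AF  — percent of each sequence covered by the union of its merged
  alignment intervals (each base counted once);
* AAI — unweighted mean identity over bidirectional best-hit protein pairs;
* shared-gene fraction — best-hit coverage of the smaller-proteome genome.

A small gapless seed-and-extend aligner (`local_align_all`) makes the
synthetic test regime self-contained: it is exact for substitution-mutated
homologs, which is all the synthetic generator emits. It is not a general
aligner (no gaps, forward strand only).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "AlignmentRecord",
    "local_align_all",
    "records_to_frame",
    "compute_ani_af",
    "compute_aai",
    "merge_intervals",
]


@dataclass
class AlignmentRecord:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    qstart: int  # 1-based inclusive
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float


def records_to_frame(records: list[AlignmentRecord]) -> pd.DataFrame:
    from .catalog import ALIGNMENT_COLUMNS

    return pd.DataFrame([vars(r) for r in records], columns=ALIGNMENT_COLUMNS)


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i : i + k], []).append(i)
    return idx


def _extend(q: str, s: str, i: int, j: int, k: int, xdrop: int) -> tuple[int, int]:
    """Gapless X-drop extension of the seed q[i:i+k] == s[j:j+k].

    Scoring +1 match / -2 mismatch. Returns (left, right): the 0-based
    half-open query interval [left, right) of the best-scoring extension
    (the subject interval is the same span shifted by j - i).
    """
    # rightward
    score = k
    best = score
    right = i + k
    x, y = i + k, j + k
    while x < len(q) and y < len(s):
        score += 1 if q[x] == s[y] else -2
        if score > best:
            best = score
            right = x + 1
        if best - score > xdrop:
            break
        x += 1
        y += 1
    # leftward
    score = best
    left = i
    x, y = i - 1, j - 1
    while x >= 0 and y >= 0:
        score += 1 if q[x] == s[y] else -2
        if score > best:
            best = score
            left = x
        if best - score > xdrop:
            break
        x -= 1
        y -= 1
    return left, right


def local_align_all(
    sequences: dict[str, str],
    k: int = 11,
    min_hit_len: int = 25,
    xdrop: int = 10,
) -> list[AlignmentRecord]:
    """All-vs-all gapless seed-and-extend alignment (forward strand).

    Shared exact k-mers seed ungapped X-drop extensions; seeds falling
    inside an interval already reported on the same diagonal are skipped;
    alignments shorter than ``min_hit_len`` are dropped. One record set is
    emitted per unordered pair (query = first id in input order).
    """
    ids = list(sequences)
    indexes = {i: _kmer_index(sequences[i], k) for i in ids}
    records: list[AlignmentRecord] = []
    for a_pos, qid in enumerate(ids):
        q = sequences[qid]
        for sid in ids[a_pos + 1 :]:
            s = sequences[sid]
            sidx = indexes[sid]
            found: dict[int, list[tuple[int, int]]] = {}  # diagonal -> q intervals
            for i in range(len(q) - k + 1):
                positions = sidx.get(q[i : i + k])
                if not positions:
                    continue
                for j in positions:
                    d = i - j
                    covered = False
                    for a, b in found.get(d, ()):
                        if a <= i and i + k <= b:
                            covered = True
                            break
                    if covered:
                        continue
                    left, right = _extend(q, s, i, j, k, xdrop)
                    found.setdefault(d, []).append((left, right))
                    length = right - left
                    if length < min_hit_len:
                        continue
                    soff = j - i
                    mism = sum(
                        1
                        for x in range(left, right)
                        if q[x] != s[x + soff]
                    )
                    records.append(
                        AlignmentRecord(
                            query_id=qid,
                            subject_id=sid,
                            percent_identity=100.0 * (length - mism) / length,
                            alignment_length=length,
                            mismatches=mism,
                            gap_opens=0,
                            qstart=left + 1,
                            qend=right,
                            sstart=left + soff + 1,
                            send=right + soff,
                            evalue=0.0,
                            bitscore=float(length - 3 * mism),
                        )
                    )
    return records


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and disjoint."""
    if not intervals:
        return []
    out = []
    for a, b in sorted(intervals):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(list(records))


def compute_ani_af(records, lengths: dict[str, int]) -> pd.DataFrame:
    """Reduce alignment records to per-pair ANI and aligned fractions.

    Per unordered genome pair: alignment intervals are merged separately on
    each genome (every base counted once) to give the aligned fractions,
    while ANI is the mean of per-record identities weighted by the raw
    alignment lengths. Pair orientation is canonicalized so that
    ``query_id < subject_id``. Pairs without records are absent from the
    output. Ids missing from ``lengths`` raise ``KeyError``.
    """
    df = _as_frame(records)
    rows = []
    if df.empty:
        return pd.DataFrame(
            columns=["query_id", "subject_id", "ani", "af_query", "af_subject", "n_alignments"]
        )
    for gid in pd.unique(df[["query_id", "subject_id"]].values.ravel()):
        if gid not in lengths:
            raise KeyError(f"no length known for sequence {gid!r}")
    for (a, b), grp in df.groupby(
        [df[["query_id", "subject_id"]].min(axis=1), df[["query_id", "subject_id"]].max(axis=1)]
    ):
        if a == b:
            continue  # self-alignments carry no pair information
        a_iv, b_iv = [], []
        wsum = isum = 0.0
        for r in grp.itertuples():
            if r.query_id == a:
                qa, qb, sa, sb = r.qstart, r.qend, r.sstart, r.send
            else:
                qa, qb, sa, sb = r.sstart, r.send, r.qstart, r.qend
            # minus-strand subject coordinates arrive reversed
            a_iv.append((min(qa, qb) - 1, max(qa, qb)))
            b_iv.append((min(sa, sb) - 1, max(sa, sb)))
            wsum += r.alignment_length
            isum += r.percent_identity * r.alignment_length
        cov_a = sum(e - s for s, e in merge_intervals(a_iv))
        cov_b = sum(e - s for s, e in merge_intervals(b_iv))
        rows.append(
            {
                "query_id": a,
                "subject_id": b,
                "ani": isum / wsum,
                "af_query": 100.0 * cov_a / lengths[a],
                "af_subject": 100.0 * cov_b / lengths[b],
                "n_alignments": len(grp),
            }
        )
    return pd.DataFrame(rows)


def _best_hits(df: pd.DataFrame) -> pd.DataFrame:
    """One best hit per query: max bitscore, ties by lower e-value then
    lexicographic subject id."""
    ranked = df.sort_values(
        ["query_id", "bitscore", "evalue", "subject_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return ranked.drop_duplicates("query_id", keep="first")


def compute_aai(
    records,
    gene_counts: dict[str, int],
    protein_genome: dict[str, str],
    bidirectional: bool = True,
) -> pd.DataFrame:
    """Reduce protein alignment records to per-genome-pair AAI statistics.

    ``protein_genome`` maps protein id to its genome of origin. Per genome
    pair, the best hit of each query protein is taken by bitscore; AAI is
    the unweighted mean identity over bidirectional best-hit pairs (mean of
    the two directed identities per pair), or over one-way best hits when
    ``bidirectional=False``. The shared-gene fraction is the percentage of
    the smaller-proteome genome's proteins that have a best hit in the
    other. Pairs without cross-hits are absent.
    """
    df = _as_frame(records)
    if df.empty:
        return pd.DataFrame(
            columns=["genome_a", "genome_b", "aai", "shared_gene_fraction", "n_hits"]
        )
    df = df.copy()
    for col, new in (("query_id", "qgenome"), ("subject_id", "sgenome")):
        try:
            df[new] = df[col].map(lambda p: protein_genome[p])
        except KeyError as exc:
            raise KeyError(f"protein {exc} has no genome mapping") from None
    for g in set(df["qgenome"]) | set(df["sgenome"]):
        if g not in gene_counts:
            raise KeyError(f"unknown genome id {g!r}")
    df = df[df["qgenome"] != df["sgenome"]]
    rows = []
    pair_key = df.apply(lambda r: tuple(sorted((r["qgenome"], r["sgenome"]))), axis=1)
    for (ga, gb), grp in df.groupby(pair_key):
        fwd = _best_hits(grp[grp["qgenome"] == ga])
        rev = _best_hits(grp[grp["qgenome"] == gb])
        fwd_map = dict(zip(fwd["query_id"], fwd["subject_id"]))
        rev_map = dict(zip(rev["query_id"], rev["subject_id"]))
        fwd_ident = dict(zip(fwd["query_id"], fwd["percent_identity"]))
        rev_ident = dict(zip(rev["query_id"], rev["percent_identity"]))
        if bidirectional:
            identities = [
                (fwd_ident[p] + rev_ident[q]) / 2.0
                for p, q in fwd_map.items()
                if rev_map.get(q) == p
            ]
        else:
            identities = list(fwd_ident.values())
        if not identities:
            continue
        small = ga if gene_counts[ga] <= gene_counts[gb] else gb
        n_with_hit = len(fwd_map) if small == ga else len(rev_map)
        rows.append(
            {
                "genome_a": ga,
                "genome_b": gb,
                "aai": sum(identities) / len(identities),
                "shared_gene_fraction": 100.0 * n_with_hit / gene_counts[small],
                "n_hits": len(grp),
            }
        )
    return pd.DataFrame(rows)
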