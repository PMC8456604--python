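"""5′ RACE amplicon processing: merge → demultiplex → V/J assignment → CDR3.

The processing chain mirrors a standard AIRR-seq workflow for a 5′ RACE
TCRγ library: overlapping read pairs are merged into full-length amplicons,
demultiplexed by the 12-nt barcode adjacent to the Cγ primer, deduplicated
to unique V-region nucleotide sequences, assigned an optimal germline V and
J by seeded alignment, purged of rearrangements using pseudogene/ORF V
segments, and reduced to clonotypes — unique (sample, V, J, CDR3-nt)
combinations.  CDR3γ is delimited by the nucleotide motifs encoding the
Tyr(Tyr/His)Cys anchor at the V side and the Phe-Gly-X-Gly anchor at the J
side; the anchor codons themselves are excluded.  A CDR3 is productive when
its length is a multiple of three and its translation is stop-free.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import edlib
import numpy as np
import pandas as pd

from .germline import (
    J_FGXG_PATTERN,
    GermlineDatabase,
    GermlineError,
    revcomp,
    translate_nt,
)
from .simulate import BARCODE_LEN, FastqRead

V_ANCHOR_PATTERN = re.compile(r"TAC[TC]A[TC]TG[TC]")

# local-alignment scoring applied to candidate alignment paths
MATCH_SCORE = 1
MISMATCH_SCORE = -2
GAP_OPEN = -4
GAP_EXTEND = -1

CLONOTYPE_COLUMNS = ["sequence_id", "sample_id", "v_call", "j_call", "cdr3",
                     "cdr3_aa", "productive", "duplicate_count", "sequence"]


@dataclass
class MergedRead:
    seq: str
    qual: str
    overlap_len: int
    overlap_mismatches: int
    id_r1: str
    id_r2: str


@dataclass
class VJAssignment:
    v_id: str
    j_id: str
    v_score: int
    j_score: int
    v_identity: float
    j_identity: float
    v_read_span: Tuple[int, int]   # half-open on the read
    j_read_span: Tuple[int, int]
    v_germline_end: int            # germline coordinate of last aligned V base


@dataclass
class PipelineConfig:
    barcodes: Dict[str, str]
    min_overlap: int = 10
    max_mismatch_ratio: float = 0.25
    barcode_max_mismatch: int = 1
    primer_len: int = 30           # retained Cγ primer-site bases stripped with the barcode
    min_v_identity: float = 0.80
    min_v_span: int = 50
    min_j_span: int = 20
    seed_k: int = 12
    v_motif_window: int = 54


# ---------------------------------------------------------------------------
# Pair merging
# ---------------------------------------------------------------------------


def merge_pairs(
    r1: FastqRead,
    r2: FastqRead,
    min_overlap: int = 10,
    max_mismatch_ratio: float = 0.25,
) -> Optional[MergedRead]:
    """Merge an overlapping read pair into one amplicon sequence.

    R2 is reverse-complemented and slid against R1; the longest overlap
    whose mismatch fraction is within ``max_mismatch_ratio`` wins.  At
    overlap mismatches the higher-quality base is taken.  Returns ``None``
    when no admissible overlap exists.
    """
    if not r1.seq or not r2.seq:
        return None
    s2 = revcomp(r2.seq)
    q2 = r2.qual[::-1]
    a = np.frombuffer(r1.seq.encode(), dtype=np.uint8)
    b = np.frombuffer(s2.encode(), dtype=np.uint8)
    best = None
    for o in range(min(len(a), len(b)), min_overlap - 1, -1):
        mm = int(np.count_nonzero(a[len(a) - o:] != b[:o]))
        if mm <= max_mismatch_ratio * o:
            best = (o, mm)
            break
    if best is None:
        return None
    o, mm = best
    head = r1.seq[: len(a) - o]
    head_q = r1.qual[: len(a) - o]
    ov_seq = []
    ov_q = []
    for k in range(o):
        i1 = len(a) - o + k
        c1, c2 = r1.seq[i1], s2[k]
        p1, p2 = r1.qual[i1], q2[k]
        if c1 == c2 or p1 >= p2:
            ov_seq.append(c1)
            ov_q.append(max(p1, p2) if c1 == c2 else p1)
        else:
            ov_seq.append(c2)
            ov_q.append(p2)
    tail = s2[o:]
    tail_q = q2[o:]
    return MergedRead(head + "".join(ov_seq) + tail, head_q + "".join(ov_q) + tail_q,
                      o, mm, r1.id, r2.id)


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def demultiplex(
    seq: str,
    barcodes: Dict[str, str],
    max_mismatch: int = 1,
    primer_len: int = 0,
) -> Tuple[Optional[str], str]:
    """Assign a merged amplicon to a sample by its 3′ barcode.

    The amplicon in mRNA (V→C) orientation ends with the reverse complement
    of the sample barcode; a C→V oriented sequence starts with the barcode
    itself and is re-oriented first.  The returned insert has the barcode
    and ``primer_len`` bases of the Cγ primer site removed.  Returns
    ``(None, seq)`` when no barcode matches within ``max_mismatch``.
    """
    codes = sorted(barcodes.items())
    ids = [s for s, _ in codes]
    for i in range(len(codes)):
        for j in range(i + 1, len(codes)):
            if _hamming(codes[i][1], codes[j][1]) <= 2 * max_mismatch:
                raise ValueError(
                    f"barcodes for {ids[i]} and {ids[j]} are too similar for "
                    f"max_mismatch={max_mismatch}")
    if len(seq) < BARCODE_LEN + primer_len:
        return None, seq
    tail = revcomp(seq[-BARCODE_LEN:])
    head = seq[:BARCODE_LEN]
    best = None  # (mismatches, sample, reoriented)
    for sample, bc in codes:
        for candidate, reorient in ((tail, False), (head, True)):
            d = _hamming(candidate, bc)
            if best is None or d < best[0]:
                best = (d, sample, reorient)
    if best is None or best[0] > max_mismatch:
        return None, seq
    _, sample, reorient = best
    if reorient:
        seq = revcomp(seq)
    return sample, seq[: len(seq) - BARCODE_LEN - primer_len]


# ---------------------------------------------------------------------------
# V/J assignment
# ---------------------------------------------------------------------------


def _parse_cigar(cigar: str) -> List[Tuple[int, str]]:
    return [(int(n), op) for n, op in re.findall(r"(\d+)([=XID])", cigar)]


def _path_stats(ops: Sequence[Tuple[int, str]]) -> Tuple[int, float]:
    """(alignment score, identity) of an alignment path."""
    matches = mismatches = columns = 0
    score = 0
    for n, op in ops:
        columns += n
        if op == "=":
            matches += n
            score += MATCH_SCORE * n
        elif op == "X":
            mismatches += n
            score += MISMATCH_SCORE * n
        else:  # I or D: one gap run
            score += GAP_OPEN + GAP_EXTEND * n
    return score, (matches / columns if columns else 0.0)


class VJAligner:
    """Seeded alignment of reads to the germline V and J inventories.

    Candidate V segments are shortlisted by exact shared k-mers (k =
    ``seed_k``), then each candidate is aligned into the read
    (semi-global); candidates are ranked by alignment score under the
    +1/−2 match/mismatch and −4/−1 gap open/extend scheme applied to the
    alignment path, with ties broken by identity then id.
    """

    def __init__(self, db: GermlineDatabase, seed_k: int = 12):
        self.db = db
        self.seed_k = seed_k
        self._index: Dict[str, set] = {}
        for seg in db.by_kind("V"):
            s = seg.seq_nt
            for pos in range(len(s) - seed_k + 1):
                self._index.setdefault(s[pos : pos + seed_k], set()).add(seg.id)

    def _candidates(self, seq: str) -> List[str]:
        k = self.seed_k
        found = set()
        for pos in range(0, len(seq) - k + 1, 4):
            found |= self._index.get(seq[pos : pos + k], set())
        return sorted(found)

    def assign(
        self,
        seq: str,
        min_v_identity: float = 0.80,
        min_v_span: int = 50,
        min_j_span: int = 20,
    ) -> Optional[VJAssignment]:
        if len(seq) < min_v_span:
            return None
        best_v = None
        for v_id in self._candidates(seq):
            germ = self.db[v_id].seq_nt
            res = edlib.align(germ, seq, mode="HW", task="path")
            ops = _parse_cigar(res["cigar"])
            # trailing germline-only bases = exonuclease-trimmed V 3' end
            trailing = 0
            while ops and ops[-1][1] == "I":
                trailing += ops[-1][0]
                ops = ops[:-1]
            score, identity = _path_stats(ops)
            start, end_incl = res["locations"][0]
            span = (start, end_incl + 1)
            if span[1] - span[0] < min_v_span or identity < min_v_identity:
                continue
            key = (-score, -identity, v_id)
            if best_v is None or key < best_v[0]:
                best_v = (key, v_id, score, identity, span, len(germ) - trailing)
        if best_v is None:
            return None
        _, v_id, v_score, v_ident, v_span, v_germ_end = best_v

        sub = seq[v_span[1]:]
        best_j = None
        for j in self.db.by_kind("J"):
            if not sub:
                break
            res = edlib.align(j.seq_nt, sub, mode="HW", task="path")
            ops = _parse_cigar(res["cigar"])
            leading = 0
            while ops and ops[0][1] == "I":   # trimmed J 5' end
                leading += ops[0][0]
                ops = ops[1:]
            score, identity = _path_stats(ops)
            start, end_incl = res["locations"][0]
            span = (v_span[1] + start, v_span[1] + end_incl + 1)
            if span[1] - span[0] < min_j_span:
                continue
            key = (-score, -identity, j.id)
            if best_j is None or key < best_j[0]:
                best_j = (key, j.id, score, identity, span)
        if best_j is None:
            return None
        _, j_id, j_score, j_ident, j_span = best_j
        return VJAssignment(v_id, j_id, v_score, j_score, v_ident, j_ident,
                            v_span, j_span, v_germ_end)


def assign_vj(
    seq: str,
    db: GermlineDatabase,
    min_v_identity: float = 0.80,
    min_v_span: int = 50,
    min_j_span: int = 20,
    seed_k: int = 12,
) -> Optional[VJAssignment]:
    """Assign optimal germline V and J segments to one sequence.

    The aligner index is cached on the database object.
    """
    aligner = getattr(db, "_vj_aligner", None)
    if aligner is None or aligner.seed_k != seed_k:
        aligner = VJAligner(db, seed_k)
        db._vj_aligner = aligner
    return aligner.assign(seq, min_v_identity, min_v_span, min_j_span)


# ---------------------------------------------------------------------------
# Filters, CDR3 extraction, clonotypes
# ---------------------------------------------------------------------------


def filter_pseudo_orf(records: pd.DataFrame, db: GermlineDatabase
                      ) -> Tuple[pd.DataFrame, int]:
    """Keep only records whose assigned V segment is potentially functional."""
    if records.empty:
        return records, 0
    for v_id in records["v_call"].unique():
        if v_id not in db:
            raise GermlineError(f"assigned V {v_id!r} absent from the germline database")
    keep = records["v_call"].map(lambda v: db[v].functionality == "functional")
    return records[keep].reset_index(drop=True), int((~keep).sum())


def extract_cdr3(seq: str, asn: VJAssignment, v_motif_window: int = 54) -> Optional[str]:
    """CDR3γ nucleotides strictly between the V- and J-side anchor motifs.

    The V-side anchor is the *last* Tyr(Tyr/His)Cys motif within
    ``v_motif_window`` bp upstream of the V alignment end (allowing the
    motif to extend up to 9 nt past it); the J-side anchor is the *first*
    Phe-Gly-X-Gly motif after the V anchor.  Anchor codons are excluded.
    """
    v_end = asn.v_read_span[1]
    lo = max(0, v_end - v_motif_window)
    hi = min(len(seq), v_end + 9)
    v_anchor_end = None
    for m in V_ANCHOR_PATTERN.finditer(seq, lo, hi):
        v_anchor_end = m.end()  # last match in the window wins
    if v_anchor_end is None:
        return None
    mj = J_FGXG_PATTERN.search(seq, v_anchor_end)
    if mj is None:
        return None
    return seq[v_anchor_end : mj.start()]


def classify_productive(cdr3_nt: str) -> Tuple[bool, str]:
    """(productive, cdr3_aa): in-frame and stop-free ⇒ productive."""
    if re.fullmatch(r"[ACGT]*", cdr3_nt) is None:
        raise ValueError(f"non-DNA characters in CDR3 {cdr3_nt!r}")
    if len(cdr3_nt) % 3 != 0:
        return False, ""
    aa = translate_nt(cdr3_nt)
    if "*" in aa:
        return False, ""
    return True, aa


def dereplicate_vregion(items: Iterable[Tuple[str, str]]) -> pd.DataFrame:
    """Exact-string deduplication of (sample_id, sequence) pairs with counts."""
    counts: Dict[Tuple[str, str], int] = {}
    for sample_id, seq in items:
        counts[(sample_id, seq)] = counts.get((sample_id, seq), 0) + 1
    rows = [{"sample_id": s, "sequence": q, "duplicate_count": c}
            for (s, q), c in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["sample_id", "sequence", "duplicate_count"])


def collapse_clonotypes(records: pd.DataFrame) -> pd.DataFrame:
    """One clonotype per distinct (sample, V, J, CDR3-nt).

    ``duplicate_count`` is summed; the representative sequence is the
    highest-count member (ties: lexicographically smallest sequence).
    Productivity and the CDR3 peptide are recomputed on the collapsed key,
    so the operation is idempotent.
    """
    if records.empty:
        return pd.DataFrame(columns=CLONOTYPE_COLUMNS)
    rows = []
    grouped = records.groupby(["sample_id", "v_call", "j_call", "cdr3"], sort=True)
    for idx, ((sample, v, j, cdr3), grp) in enumerate(grouped):
        rep = grp.sort_values(["duplicate_count", "sequence"],
                              ascending=[False, True]).iloc[0]
        productive, aa = classify_productive(cdr3)
        rows.append({
            "sequence_id": f"clonotype:{idx:06d}", "sample_id": sample,
            "v_call": v, "j_call": j, "cdr3": cdr3, "cdr3_aa": aa,
            "productive": productive,
            "duplicate_count": int(grp["duplicate_count"].sum()),
            "sequence": rep["sequence"],
        })
    return pd.DataFrame(rows, columns=CLONOTYPE_COLUMNS)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

STAGE_COLUMNS = ["sample_id", "demultiplexed", "unique_vregion", "vj_assigned",
                 "functional_v", "cdr3_extracted", "clonotypes", "productive"]


def run_pipeline(
    cfg: PipelineConfig,
    db: GermlineDatabase,
    r1: Sequence[FastqRead],
    r2: Sequence[FastqRead],
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, int]]:
    """Run the full chain and return (clonotypes, per-sample stage report, totals).

    Totals cover the pre-demultiplex stages: input pairs, merged, and reads
    assigned to a sample.  Per-sample counts are monotone non-increasing
    along the filter chain; every drop is accounted.
    """
    if len(r1) != len(r2):
        raise ValueError("R1/R2 read counts differ")
    totals = {"pairs": len(r1), "merged": 0, "demultiplexed": 0}

    merged: List[MergedRead] = []
    for a, b in zip(r1, r2):
        m = merge_pairs(a, b, cfg.min_overlap, cfg.max_mismatch_ratio)
        if m is not None:
            merged.append(m)
    totals["merged"] = len(merged)

    demuxed: List[Tuple[str, str]] = []
    for m in merged:
        sample, insert = demultiplex(m.seq, cfg.barcodes,
                                     cfg.barcode_max_mismatch, cfg.primer_len)
        if sample is not None:
            demuxed.append((sample, insert))
    totals["demultiplexed"] = len(demuxed)

    unique = dereplicate_vregion(demuxed)

    assigned_rows = []
    for row in unique.itertuples(index=False):
        asn = assign_vj(row.sequence, db, cfg.min_v_identity,
                        cfg.min_v_span, cfg.min_j_span, cfg.seed_k)
        if asn is None:
            continue
        assigned_rows.append({
            "sample_id": row.sample_id, "sequence": row.sequence,
            "duplicate_count": row.duplicate_count,
            "v_call": asn.v_id, "j_call": asn.j_id, "asn": asn,
        })
    assigned = pd.DataFrame(
        assigned_rows,
        columns=["sample_id", "sequence", "duplicate_count", "v_call", "j_call", "asn"])

    functional, _ = filter_pseudo_orf(assigned, db)

    cdr3s = []
    for row in functional.itertuples(index=False):
        cdr3s.append(extract_cdr3(row.sequence, row.asn, cfg.v_motif_window))
    functional = functional.assign(cdr3=cdr3s)
    extracted = functional[functional["cdr3"].notna()].drop(columns=["asn"])

    clonotypes = collapse_clonotypes(extracted)

    samples = sorted(cfg.barcodes)
    report_rows = []
    for s in samples:
        report_rows.append({
            "sample_id": s,
            "demultiplexed": sum(1 for smp, _ in demuxed if smp == s),
            "unique_vregion": int((unique["sample_id"] == s).sum()),
            "vj_assigned": int((assigned["sample_id"] == s).sum()) if not assigned.empty else 0,
            "functional_v": int((functional["sample_id"] == s).sum()) if not functional.empty else 0,
            "cdr3_extracted": int((extracted["sample_id"] == s).sum()) if not extracted.empty else 0,
            "clonotypes": int((clonotypes["sample_id"] == s).sum()) if not clonotypes.empty else 0,
            "productive": int(clonotypes.loc[clonotypes["sample_id"] == s, "productive"].sum())
            if not clonotypes.empty else 0,
        })
    report = pd.DataFrame(report_rows, columns=STAGE_COLUMNS)
    return clonotypes, report, totals


def evaluate_against_truth(
    cfg: PipelineConfig,
    db: GermlineDatabase,
    r1: Sequence[FastqRead],
    r2: Sequence[FastqRead],
    truth: pd.DataFrame,
) -> Dict[str, float]:
    """Per-read recovery of simulated ground truth through the chain.

    Each pair is merged, demultiplexed, assigned and CDR3-extracted
    individually, then compared with its truth row.  Returns fractions over
    reads that survive to assignment (``assigned``), with correct V, J,
    CDR3 and sample calls.
    """
    n = assigned = v_ok = j_ok = cdr3_ok = sample_ok = 0
    rows = {t.read_id: t for t in truth.itertuples(index=False)}
    for a, b in zip(r1, r2):
        t = rows[a.id]
        n += 1
        m = merge_pairs(a, b, cfg.min_overlap, cfg.max_mismatch_ratio)
        if m is None:
            continue
        sample, insert = demultiplex(m.seq, cfg.barcodes,
                                     cfg.barcode_max_mismatch, cfg.primer_len)
        if sample is None:
            continue
        asn = assign_vj(insert, db, cfg.min_v_identity, cfg.min_v_span,
                        cfg.min_j_span, cfg.seed_k)
        if asn is None:
            continue
        assigned += 1
        sample_ok += sample == t.sample_id
        v_ok += asn.v_id == t.v_id
        j_ok += asn.j_id == t.j_id
        cdr3_ok += extract_cdr3(insert, asn, cfg.v_motif_window) == t.cdr3_nt_truth
    if assigned == 0:
        raise RuntimeError("no reads survived to V/J assignment")
    return {
        "n_reads": n, "assigned": assigned,
        "v_accuracy": v_ok / assigned, "j_accuracy": j_ok / assigned,
        "cdr3_accuracy": cdr3_ok / assigned, "sample_accuracy": sample_ok / assigned,
    }
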