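"""V-J recombination read simulator with ground truth.

Emulates the structure of a 5′ RACE TCRγ amplicon library: each transcript
is a 5′ UTR + leader + (possibly trimmed) V-REGION + junction + (possibly
trimmed) J-REGION + a retained Cγ exon-1 prefix, and the sequenced amplicon
carries the reverse complement of a 12-nt sample barcode at its 3′ end (the
barcode sits at the 5′ end of the gene-specific primer).  Junctional
diversity follows standard recombination biology: exonucleolytic trimming
at the V 3′ and J 5′ ends (truncated-geometric lengths), palindromic (P)
nucleotides only at untrimmed ends, and non-templated (N) insertions.
Paired 250-bp reads are drawn from both amplicon ends with an optional
per-base substitution error; amplicons are kept shorter than two read
lengths so the mates always overlap and can be merged.

Every emitted read is paired with a :class:`TruthRecord`, so pipeline
accuracy can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .germline import GermlineDatabase, GermlineError, revcomp, translate_nt
from .reference import UTR_SEQ

BARCODE_LEN = 12

#: default sample barcodes — pairwise Hamming distance 12
DEFAULT_BARCODES: Dict[str, str] = {
    "S1": "AAACCCGGGTTT",
    "S2": "GGGTTTAAACCC",
    "S3": "CCCAAATTTGGG",
    "S4": "TTTGGGCCCAAA",
}

#: V/J usage observed in the thymus repertoire: the four dominant V
#: segments plus the two rare functional Vγ4 members carry their reported
#: frequencies; the remaining functional V segments share the rest equally.
REPORTED_V_USAGE = {"Vg3.7": 0.2058, "Vg2.13": 0.1984, "Vg1.6": 0.1600,
                    "Vg1.3": 0.1015, "Vg4.1": 0.0019, "Vg4.3": 0.0003}
REPORTED_J_USAGE = {"Jg1": 0.3558, "Jg2": 0.2204, "Jg3": 0.4238}


class FastqRead(Tuple[str, str, str]):
    """Lightweight FASTQ record: (id, sequence, quality)."""

    __slots__ = ()

    def __new__(cls, read_id: str, seq: str, qual: str):
        return tuple.__new__(cls, (read_id, seq, qual))

    @property
    def id(self) -> str:
        return self[0]

    @property
    def seq(self) -> str:
        return self[1]

    @property
    def qual(self) -> str:
        return self[2]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated library."""

    v_weights: Optional[Dict[str, float]] = None     # default: reported usage
    j_weights: Optional[Dict[str, float]] = None
    vj_weights: Optional[Dict[Tuple[str, str], float]] = None  # joint override
    trim_geom_p: float = 0.35      # geometric parameter, per trimmed end
    trim_max: int = 10
    p_nt_max: int = 2
    n_len_geom_p: float = 0.15
    n_max: int = 15
    subst_error_rate: float = 0.0
    read_len: int = 250
    amplicon_c_prefix_len: int = 30
    utr_len: int = 12
    barcodes: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_BARCODES))
    n_sequences: int = 1000
    seed: int = 1

    def __post_init__(self) -> None:
        if self.read_len < 50:
            raise ValueError("read_len must be >= 50")
        for p in (self.trim_geom_p, self.n_len_geom_p):
            if not 0 < p <= 1:
                raise ValueError("geometric parameters must be in (0, 1]")
        if not 0 <= self.subst_error_rate < 1:
            raise ValueError("subst_error_rate must be in [0, 1)")
        for sample, bc in self.barcodes.items():
            if len(bc) != BARCODE_LEN:
                raise ValueError(f"barcode for {sample} is not {BARCODE_LEN} nt")
        if len(set(self.barcodes.values())) != len(self.barcodes):
            raise ValueError("duplicate barcodes across samples")


@dataclass
class TruthRecord:
    """Ground truth of one simulated rearrangement."""

    read_id: str
    sample_id: str
    v_id: str
    j_id: str
    v_trim: int
    j_trim: int
    p_v: str
    n_insert: str
    p_j: str
    cdr3_nt_truth: str
    productive_truth: bool

    def __post_init__(self) -> None:
        if self.v_trim > 0 and self.p_v:
            raise ValueError("P nucleotides require an untrimmed V end")
        if self.j_trim > 0 and self.p_j:
            raise ValueError("P nucleotides require an untrimmed J end")


TRUTH_COLUMNS = ["read_id", "sample_id", "v_id", "j_id", "v_trim", "j_trim",
                 "p_v", "n_insert", "p_j", "cdr3_nt_truth", "productive_truth"]


def default_weights(db: GermlineDatabase) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Reported-usage V weights and J weights over the functional segments."""
    func_v = [s.id for s in db.functional("V")]
    v_weights = {}
    rest = [v for v in func_v if v not in REPORTED_V_USAGE]
    remainder = 1.0 - sum(REPORTED_V_USAGE.values())
    for v in func_v:
        v_weights[v] = REPORTED_V_USAGE.get(v, remainder / len(rest) if rest else 0.0)
    func_j = [s.id for s in db.functional("J")]
    j_weights = {j: REPORTED_J_USAGE.get(j, 0.0) for j in func_j}
    if set(func_j) != set(REPORTED_J_USAGE):
        j_weights = {j: 1.0 / len(func_j) for j in func_j}
    return v_weights, j_weights


def _normalize(weights: Dict, db: GermlineDatabase, kind: str) -> Tuple[List, np.ndarray]:
    keys = sorted(weights)
    for key in keys:
        ids = key if isinstance(key, tuple) else (key,)
        for seg_id in ids:
            if db[seg_id].functionality != "functional":
                raise GermlineError(f"weight references non-functional segment {seg_id}")
    probs = np.array([weights[k] for k in keys], dtype=float)
    total = probs.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"{kind} weights sum to {total}, expected 1")
    return keys, probs / total


def _trunc_geometric(rng: np.random.Generator, p: float, cap: int) -> int:
    """min(G, cap) with G geometric on {0, 1, ...}."""
    return min(int(rng.geometric(p)) - 1, cap)


def _utr(cfg: SimulationConfig) -> str:
    reps = -(-cfg.utr_len // len(UTR_SEQ))
    return (UTR_SEQ * reps)[: cfg.utr_len]


def is_productive_cdr3(cdr3_nt: str) -> bool:
    """In-frame (length ≡ 0 mod 3) and stop-free."""
    return len(cdr3_nt) % 3 == 0 and "*" not in translate_nt(cdr3_nt)


class RearrangementSampler:
    """Draws V-J rearrangements from a config + germline database."""

    def __init__(self, cfg: SimulationConfig, db: GermlineDatabase):
        if not db.usable_for_pipeline:
            raise GermlineError("database lacks functional V and J segments")
        self.cfg = cfg
        self.db = db
        if cfg.vj_weights is not None:
            self._pairs, self._pair_probs = _normalize(cfg.vj_weights, db, "V-J")
            self._v_keys = self._j_keys = None
        else:
            v_w, j_w = cfg.v_weights, cfg.j_weights
            if v_w is None or j_w is None:
                dv, dj = default_weights(db)
                v_w, j_w = v_w or dv, j_w or dj
            self._v_keys, self._v_probs = _normalize(v_w, db, "V")
            self._j_keys, self._j_probs = _normalize(j_w, db, "J")
            self._pairs = None
        self._c_prefix = db.by_kind("C")[0].seq_nt[: cfg.amplicon_c_prefix_len]

    def draw_pair(self, rng: np.random.Generator) -> Tuple[str, str]:
        if self._pairs is not None:
            idx = rng.choice(len(self._pairs), p=self._pair_probs)
            return self._pairs[idx]
        v = self._v_keys[rng.choice(len(self._v_keys), p=self._v_probs)]
        j = self._j_keys[rng.choice(len(self._j_keys), p=self._j_probs)]
        return v, j

    def sample(self, rng: np.random.Generator) -> Tuple[str, TruthRecord]:
        """One rearranged transcript (without barcode) and its truth record."""
        cfg = self.cfg
        v_id, j_id = self.draw_pair(rng)
        v, j = self.db[v_id], self.db[j_id]
        v_tail = v.cdr3_germline_nt
        j_head = j.cdr3_germline_nt

        # trimming never removes the anchor codons themselves
        v_trim = _trunc_geometric(rng, cfg.trim_geom_p, min(cfg.trim_max, len(v_tail)))
        j_trim = _trunc_geometric(rng, cfg.trim_geom_p, min(cfg.trim_max, len(j_head)))
        p_v = p_j = ""
        if v_trim == 0 and cfg.p_nt_max > 0:
            n_p = int(rng.integers(0, cfg.p_nt_max + 1))
            if n_p:
                p_v = revcomp(v.seq_nt[-n_p:])
        if j_trim == 0 and cfg.p_nt_max > 0:
            n_p = int(rng.integers(0, cfg.p_nt_max + 1))
            if n_p:
                p_j = revcomp(j.seq_nt[:n_p])
        n_len = _trunc_geometric(rng, cfg.n_len_geom_p, cfg.n_max)
        n_insert = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n_len))

        v_part = v.seq_nt[: len(v.seq_nt) - v_trim]
        j_part = j.seq_nt[j_trim:]
        cdr3 = v_tail[: len(v_tail) - v_trim] + p_v + n_insert + p_j + j_head[j_trim:]
        mrna = _utr(cfg) + v.leader_nt + v_part + p_v + n_insert + p_j + j_part + self._c_prefix
        truth = TruthRecord(
            read_id="", sample_id="", v_id=v_id, j_id=j_id,
            v_trim=v_trim, j_trim=j_trim, p_v=p_v, n_insert=n_insert, p_j=p_j,
            cdr3_nt_truth=cdr3, productive_truth=is_productive_cdr3(cdr3),
        )
        return mrna, truth


def sample_rearrangement(
    cfg: SimulationConfig, db: GermlineDatabase, rng: np.random.Generator
) -> Tuple[str, TruthRecord]:
    """Draw a single rearranged transcript; see :class:`RearrangementSampler`."""
    return RearrangementSampler(cfg, db).sample(rng)


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    n_hit = int(hit.sum())
    if n_hit:
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        idx_of = np.zeros(256, dtype=np.int64)
        for i, b in enumerate(b"ACGT"):
            idx_of[b] = i
        shift = rng.integers(1, 4, size=n_hit)
        arr[hit] = lut[(idx_of[arr[hit]] + shift) % 4]
    return arr.tobytes().decode()


def emit_paired_reads(
    amplicon: str, cfg: SimulationConfig, rng: np.random.Generator, read_id: str = "sim"
) -> Tuple[FastqRead, FastqRead]:
    """Paired 5′/3′ reads of one amplicon; constant Q37, substitution errors only.

    R1 reads the 5′ RACE end of the amplicon; R2 is the reverse complement
    of the 3′ end.  The amplicon must be shorter than two read lengths so
    the mates overlap (the merge step depends on it).
    """
    L, rl = len(amplicon), cfg.read_len
    if not rl <= L < 2 * rl:
        raise ValueError(
            f"amplicon length {L} outside [{rl}, {2 * rl}): mates would not overlap")
    r1 = _add_errors(amplicon[:rl], cfg.subst_error_rate, rng)
    r2 = _add_errors(revcomp(amplicon[-rl:]), cfg.subst_error_rate, rng)
    qual = "F" * rl  # Q37
    return FastqRead(read_id, r1, qual), FastqRead(read_id, r2, qual)


@dataclass
class SimulatedDataset:
    r1: List[FastqRead]
    r2: List[FastqRead]
    truth: pd.DataFrame


def simulate_dataset(cfg: SimulationConfig, db: GermlineDatabase) -> SimulatedDataset:
    """Simulate a full multiplexed paired-end run with ground truth.

    Deterministic for a given config seed: repeated calls return identical
    reads and truth rows.  Reads are assigned to samples uniformly at
    random; the sample's barcode is appended (reverse-complemented) at the
    amplicon 3′ end, as a Cγ-anchored gene-specific primer would place it.
    """
    rng = np.random.default_rng(cfg.seed)
    sampler = RearrangementSampler(cfg, db)
    samples = sorted(cfg.barcodes)
    r1_list: List[FastqRead] = []
    r2_list: List[FastqRead] = []
    truths: List[TruthRecord] = []
    for i in range(cfg.n_sequences):
        mrna, truth = sampler.sample(rng)
        sample_id = samples[int(rng.integers(0, len(samples)))]
        amplicon = mrna + revcomp(cfg.barcodes[sample_id])
        read_id = f"sim:{i:06d}"
        r1, r2 = emit_paired_reads(amplicon, cfg, rng, read_id)
        truths.append(replace(truth, read_id=read_id, sample_id=sample_id))
        r1_list.append(r1)
        r2_list.append(r2)
    truth_df = pd.DataFrame([t.__dict__ for t in truths], columns=TRUTH_COLUMNS)
    return SimulatedDataset(r1_list, r2_list, truth_df)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def write_fastq(reads: List[FastqRead], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> List[FastqRead]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(FastqRead(rec.id, str(rec.seq).upper(), qual))
    return out


def write_dataset(ds: SimulatedDataset, prefix: str) -> None:
    """Write <prefix>_R1.fastq, <prefix>_R2.fastq and <prefix>_truth.tsv."""
    write_fastq(ds.r1, f"{prefix}_R1.fastq")
    write_fastq(ds.r2, f"{prefix}_R2.fastq")
    ds.truth.to_csv(f"{prefix}_truth.tsv", sep="\t", index=False)
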