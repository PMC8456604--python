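"""Germline TCRγ gene-segment model.

The chicken TCRγ locus is a translocon: an array of Vγ segments upstream of
three Jγ segments and a single Cγ gene.  This module holds the in-memory
model of that germline inventory (segments with IMGT-style region
annotations, recombination signal sequences and functionality classes) plus
the operations the repertoire pipeline needs from it:

* loading/writing a database as FASTA + a tab-separated metadata table,
* conserved-anchor validation (1st-CYS "C23", TRP "W41", 2nd-CYS "C104"),
* IMGT functionality classification (functional / ORF / pseudogene),
* heptamer/nonamer RSS scanning,
* subgroup clustering at the ≥70 % nucleotide-identity criterion.

Coordinates are 0-based half-open throughout.  Segment ids use ASCII
canonical names ("Vg2.13", "Jg3", "Cg"); Greek rendering is a display
concern only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import edlib
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# ---------------------------------------------------------------------------
# Constants
# ---------------------------------------------------------------------------

RSS_HEPTAMER = "CACAGTG"
RSS_NONAMER = "ACAAAAACC"

#: default mismatch tolerances used when judging whether an annotated RSS is
#: intact (the classification of "defect in RSS" is conventional, not a
#: published threshold; both are configurable at the call sites).
MAX_HEPTAMER_MISMATCHES = 2
MAX_NONAMER_MISMATCHES = 3

#: nucleotide motif of the J-segment Phe-Gly-X-Gly anchor
J_FGXG_PATTERN = re.compile(r"TT[CT]GG[CA][AT][CG][AT]GG[AT]")

REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(dna: str) -> str:
    """Reverse complement of a DNA string."""
    return dna.translate(_COMPLEMENT)[::-1]


def translate_nt(dna: str) -> str:
    """Translate complete codons of ``dna`` with the standard code ('*' = stop)."""
    usable = len(dna) - len(dna) % 3
    if usable == 0:
        return ""
    return str(Seq(dna[:usable]).translate())


class GermlineError(ValueError):
    """Raised for malformed germline databases or segment annotations."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RSSHit:
    """One heptamer/spacer/nonamer recombination-signal match."""

    heptamer: str
    nonamer: str
    spacer_len: int
    heptamer_mismatches: int
    nonamer_mismatches: int
    position: int
    side: str  # "five_prime" | "three_prime"

    def __post_init__(self) -> None:
        if self.spacer_len not in (12, 23):
            raise GermlineError(f"RSS spacer must be 12 or 23, got {self.spacer_len}")
        if self.side not in ("five_prime", "three_prime"):
            raise GermlineError(f"bad RSS side {self.side!r}")

    @property
    def total_mismatches(self) -> int:
        return self.heptamer_mismatches + self.nonamer_mismatches

    def is_intact(
        self,
        max_heptamer: int = MAX_HEPTAMER_MISMATCHES,
        max_nonamer: int = MAX_NONAMER_MISMATCHES,
    ) -> bool:
        return (
            self.heptamer_mismatches <= max_heptamer
            and self.nonamer_mismatches <= max_nonamer
        )


@dataclass(frozen=True)
class GermlineSegment:
    """One germline V, J or C gene segment.

    ``seq_nt`` is the coding region: V-REGION for V segments (FR1 start
    through the germline CDR3 contribution downstream of FR3), J-REGION for
    J segments, the exon concatenation for C.  ``regions`` maps FR/CDR names
    to half-open intervals on ``seq_nt`` (V only).
    """

    id: str
    kind: str  # "V" | "J" | "C"
    seq_nt: str
    functionality: str = "functional"  # "functional" | "ORF" | "pseudo"
    subgroup: Optional[str] = None
    leader_nt: str = ""
    regions: Mapping[str, Tuple[int, int]] = field(default_factory=dict)
    rss: Optional[RSSHit] = None
    locus: Optional[Tuple[str, int, int, str]] = None  # contig, start, end, strand

    def __post_init__(self) -> None:
        if self.kind not in ("V", "J", "C"):
            raise GermlineError(f"{self.id}: segment kind must be V/J/C, got {self.kind!r}")
        if self.functionality not in ("functional", "ORF", "pseudo"):
            raise GermlineError(f"{self.id}: bad functionality {self.functionality!r}")
        self._check_regions()

    def _check_regions(self) -> None:
        prev_end = 0
        for name in REGION_ORDER:
            if name not in self.regions:
                continue
            start, end = self.regions[name]
            if not (0 <= start < end <= len(self.seq_nt)):
                raise GermlineError(f"{self.id}: region {name} interval ({start},{end}) "
                                    f"outside sequence of length {len(self.seq_nt)}")
            if start < prev_end:
                raise GermlineError(f"{self.id}: region {name} overlaps the previous region")
            prev_end = end

    # -- convenience accessors -------------------------------------------------
    @property
    def has_regions(self) -> bool:
        return all(name in self.regions for name in REGION_ORDER)

    @property
    def fr1_start(self) -> int:
        return self.regions["FR1"][0]

    @property
    def fr3_end(self) -> int:
        return self.regions["FR3"][1]

    @property
    def cdr3_germline_nt(self) -> str:
        """Germline-encoded CDR3 contribution (V: 3′ tail after the C104 codon;
        J: 5′ head before the Phe of FGXG)."""
        if self.kind == "V":
            return self.seq_nt[self.fr3_end:]
        if self.kind == "J":
            m = J_FGXG_PATTERN.search(self.seq_nt)
            if m is None:
                raise GermlineError(f"{self.id}: no Phe-Gly-X-Gly motif in J segment")
            return self.seq_nt[: m.start()]
        raise GermlineError("cdr3_germline_nt is defined for V and J segments only")


@dataclass
class AnchorReport:
    """Presence of the conserved V-domain anchor residues."""

    c23_present: bool
    w41_present: bool
    c104_present: bool
    c23_codon_start: Optional[int] = None
    w41_codon_start: Optional[int] = None
    c104_codon_start: Optional[int] = None
    frameshift: bool = False
    internal_stop: bool = False

    @property
    def all_present(self) -> bool:
        return self.c23_present and self.w41_present and self.c104_present


class GermlineDatabase:
    """Ordered, id-indexed collection of germline segments."""

    def __init__(self, segments: Iterable[GermlineSegment]):
        self.segments: List[GermlineSegment] = list(segments)
        self._by_id: Dict[str, GermlineSegment] = {}
        for seg in self.segments:
            if seg.id in self._by_id:
                raise GermlineError(f"duplicate segment id {seg.id!r}")
            self._by_id[seg.id] = seg

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __contains__(self, seg_id: str) -> bool:
        return seg_id in self._by_id

    def __getitem__(self, seg_id: str) -> GermlineSegment:
        try:
            return self._by_id[seg_id]
        except KeyError:
            raise KeyError(f"segment {seg_id!r} not in germline database") from None

    def by_kind(self, kind: str) -> List[GermlineSegment]:
        return [s for s in self.segments if s.kind == kind]

    def functional(self, kind: str) -> List[GermlineSegment]:
        return [s for s in self.segments if s.kind == kind and s.functionality == "functional"]

    @property
    def usable_for_pipeline(self) -> bool:
        """At least one functional V and one functional J."""
        return bool(self.functional("V")) and bool(self.functional("J"))

    def subgroup_of(self, v_id: str) -> Optional[str]:
        return self[v_id].subgroup


# ---------------------------------------------------------------------------
# Database I/O (FASTA + tab-separated metadata)
# ---------------------------------------------------------------------------

METADATA_COLUMNS = [
    "id", "kind", "subgroup", "functionality", "leader_end",
    "fr1_start", "fr1_end", "cdr1_end", "fr2_end", "cdr2_end", "fr3_end",
    "rss_heptamer_pos", "rss_spacer", "contig", "start", "end", "strand",
]


def _opt_int(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return int(value)


def read_germline_db(fasta_path, metadata_path) -> GermlineDatabase:
    """Load a germline database from a FASTA file and its metadata table.

    The FASTA record for a V segment is leader+V-REGION; ``leader_end``
    marks where the V-REGION begins.  Region columns are cumulative ends on
    the V-REGION.  Every segment invariant is checked on load.
    """
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise GermlineError(f"metadata missing columns: {sorted(missing_cols)}")
    meta_ids = set(meta["id"])
    for rec_id in records:
        if rec_id not in meta_ids:
            raise GermlineError(f"FASTA record {rec_id!r} has no metadata row")

    segments = []
    for row in meta.itertuples(index=False):
        if row.id not in records:
            raise GermlineError(f"metadata row {row.id!r} has no FASTA record")
        full = records[row.id]
        leader_end = _opt_int(row.leader_end) or 0
        leader, seq_nt = full[:leader_end], full[leader_end:]
        regions: Dict[str, Tuple[int, int]] = {}
        if row.kind == "V" and row.fr1_end != "":
            try:
                bounds = [int(row.fr1_start), int(row.fr1_end), int(row.cdr1_end),
                          int(row.fr2_end), int(row.cdr2_end), int(row.fr3_end)]
            except ValueError as exc:
                raise GermlineError(f"{row.id}: malformed region interval: {exc}") from None
            for name, lo, hi in zip(REGION_ORDER, bounds[:-1], bounds[1:]):
                regions[name] = (lo, hi)
        rss = None
        if row.rss_heptamer_pos != "":
            side = "three_prime" if row.kind == "V" else "five_prime"
            rss = RSSHit(RSS_HEPTAMER, RSS_NONAMER, int(row.rss_spacer), 0, 0,
                         int(row.rss_heptamer_pos), side)
        locus = None
        if row.contig != "":
            locus = (row.contig, int(row.start), int(row.end), row.strand)
        seg = GermlineSegment(
            id=row.id, kind=row.kind, seq_nt=seq_nt,
            functionality=row.functionality,
            subgroup=row.subgroup or None, leader_nt=leader,
            regions=regions, rss=rss, locus=locus,
        )
        _validate_segment(seg)
        segments.append(seg)
    return GermlineDatabase(segments)


def _validate_segment(seg: GermlineSegment) -> None:
    """Cross-field invariants beyond what the dataclass can check locally."""
    if seg.kind == "V" and seg.functionality == "functional":
        if not seg.has_regions:
            raise GermlineError(f"{seg.id}: functional V lacks region annotation")
        report = validate_anchor_residues(seg)
        if report.internal_stop or report.frameshift:
            raise GermlineError(f"{seg.id}: functional V does not translate cleanly")
        if not report.all_present:
            raise GermlineError(f"{seg.id}: functional V is missing a conserved anchor")
    if seg.kind == "J" and seg.functionality == "functional":
        if J_FGXG_PATTERN.search(seg.seq_nt) is None:
            raise GermlineError(f"{seg.id}: functional J lacks the Phe-Gly-X-Gly motif")


def write_germline_db(db: GermlineDatabase, fasta_path, metadata_path) -> None:
    """Inverse of :func:`read_germline_db`."""
    recs = [SeqRecord(Seq(s.leader_nt + s.seq_nt), id=s.id, description="") for s in db]
    SeqIO.write(recs, str(fasta_path), "fasta")
    rows = []
    for s in db:
        region_vals = [""] * 6
        if s.has_regions:
            region_vals = [s.regions["FR1"][0], s.regions["FR1"][1], s.regions["CDR1"][1],
                           s.regions["FR2"][1], s.regions["CDR2"][1], s.regions["FR3"][1]]
        rows.append({
            "id": s.id, "kind": s.kind, "subgroup": s.subgroup or "",
            "functionality": s.functionality, "leader_end": len(s.leader_nt),
            "fr1_start": region_vals[0], "fr1_end": region_vals[1],
            "cdr1_end": region_vals[2], "fr2_end": region_vals[3],
            "cdr2_end": region_vals[4], "fr3_end": region_vals[5],
            "rss_heptamer_pos": "" if s.rss is None else s.rss.position,
            "rss_spacer": "" if s.rss is None else s.rss.spacer_len,
            "contig": "" if s.locus is None else s.locus[0],
            "start": "" if s.locus is None else s.locus[1],
            "end": "" if s.locus is None else s.locus[2],
            "strand": "" if s.locus is None else s.locus[3],
        })
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Anchor validation and functionality classification
# ---------------------------------------------------------------------------


def validate_anchor_residues(seg: GermlineSegment) -> AnchorReport:
    """Check the conserved V-domain anchors on the annotated reading frame.

    By the numbering map used here the 1st-CYS ("C23") is the last codon of
    FR1, the conserved TRP ("W41") is any in-frame Trp codon within FR2, and
    the 2nd-CYS ("C104") is the last codon of FR3.  A leader or region span
    that is not a whole number of codons flags a frameshift and reports all
    anchors absent.
    """
    if seg.kind != "V":
        raise GermlineError(f"{seg.id}: anchor validation applies to V segments")
    if not seg.has_regions:
        raise GermlineError(f"{seg.id}: anchor validation requires region annotation")

    fr1 = seg.regions["FR1"]
    fr2 = seg.regions["FR2"]
    fr3 = seg.regions["FR3"]
    frame_ok = (
        len(seg.leader_nt) % 3 == 0
        and fr1[0] % 3 == 0
        and all(seg.regions[name][1] % 3 == 0 for name in REGION_ORDER)
    )
    if not frame_ok:
        return AnchorReport(False, False, False, frameshift=True)

    coding = seg.leader_nt + seg.seq_nt[: fr3[1]]
    aa = translate_nt(coding)
    internal_stop = "*" in aa

    def codon_is(pos: int, residues: str) -> bool:
        return translate_nt(seg.seq_nt[pos : pos + 3]) in residues

    c23_pos = fr1[1] - 3
    c104_pos = fr3[1] - 3
    c23 = codon_is(c23_pos, "C")
    c104 = codon_is(c104_pos, "C")
    w41 = False
    w41_pos = None
    for pos in range(fr2[0], fr2[1] - 2, 3):
        if codon_is(pos, "W"):
            w41, w41_pos = True, pos
            break
    return AnchorReport(
        c23_present=c23, w41_present=w41, c104_present=c104,
        c23_codon_start=c23_pos, w41_codon_start=w41_pos, c104_codon_start=c104_pos,
        internal_stop=internal_stop,
    )


def classify_functionality(
    seg: GermlineSegment,
    require_rss: bool = True,
    max_heptamer_mismatches: int = MAX_HEPTAMER_MISMATCHES,
    max_nonamer_mismatches: int = MAX_NONAMER_MISMATCHES,
) -> str:
    """IMGT-style functionality call for a V segment.

    pseudo: broken reading frame (internal stop or frameshift across
    leader+V).  ORF: frame intact but a conserved anchor is absent, or (with
    ``require_rss``) no intact RSS is annotated.  functional otherwise.
    """
    if seg.kind != "V":
        raise GermlineError("functionality classification applies to V segments")
    report = validate_anchor_residues(seg)
    if report.frameshift or report.internal_stop:
        return "pseudo"
    if not report.all_present:
        return "ORF"
    if require_rss:
        if seg.rss is None or not seg.rss.is_intact(max_heptamer_mismatches,
                                                    max_nonamer_mismatches):
            return "ORF"
    return "functional"


# ---------------------------------------------------------------------------
# RSS scanning
# ---------------------------------------------------------------------------


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def scan_rss(
    dna: str,
    side: str = "three_prime",
    spacer_len: int = 23,
    max_mismatches: int = 0,
) -> List[RSSHit]:
    """Scan ``dna`` for heptamer + spacer + nonamer RSS motifs.

    The scan always reads heptamer-first on the strand provided; for a 5′
    RSS (e.g. upstream of a J segment) pass the RSS-bearing strand — i.e.
    the reverse complement of the genomic top strand — so the motif again
    reads heptamer, spacer, nonamer.  Hits are sorted by total mismatches,
    then position.
    """
    dna = dna.upper()
    span = 7 + spacer_len + 9
    hits: List[RSSHit] = []
    for pos in range(0, len(dna) - span + 1):
        hept = dna[pos : pos + 7]
        nona = dna[pos + 7 + spacer_len : pos + span]
        hm = _mismatches(hept, RSS_HEPTAMER)
        if hm > max_mismatches:
            continue
        nm = _mismatches(nona, RSS_NONAMER)
        if nm > max_mismatches:
            continue
        hits.append(RSSHit(hept, nona, spacer_len, hm, nm, pos, side))
    hits.sort(key=lambda h: (h.total_mismatches, h.position))
    return hits


# ---------------------------------------------------------------------------
# Pairwise identity and subgroup clustering
# ---------------------------------------------------------------------------


def alignment_identity(a: str, b: str) -> float:
    """Global (end-gap-penalized) alignment identity: matches / alignment columns."""
    if not a or not b:
        raise GermlineError("alignment identity of an empty sequence is undefined")
    res = edlib.align(a.upper(), b.upper(), mode="NW", task="path")
    matches = columns = 0
    for count, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        n = int(count)
        columns += n
        if op == "=":
            matches += n
    return matches / columns


def cluster_subgroups(
    v_segments: Sequence[GermlineSegment],
    identity_threshold: float = 0.70,
) -> Tuple[Dict[str, str], List[str]]:
    """Single-linkage clustering of V segments into subgroups.

    Identity is computed over FR1 start through FR3 end (the same span used
    for phylogenetic comparisons); two segments join the same subgroup when
    identity ≥ ``identity_threshold`` (inclusive), transitively.  Cluster
    labels "Vg1", "Vg2", … are assigned in 3′→5′ order of each cluster's
    3′-most member, so the labelling is invariant under input permutation.
    Returns ``(labels, excluded_ids)`` where excluded segments lack region
    annotation.
    """
    usable = [s for s in v_segments if s.kind == "V" and s.has_regions]
    excluded = [s.id for s in v_segments if not (s.kind == "V" and s.has_regions)]
    if not usable:
        return {}, excluded
    usable = sorted(usable, key=lambda s: s.id)
    spans = [s.seq_nt[s.fr1_start : s.fr3_end] for s in usable]

    parent = list(range(len(usable)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            if alignment_identity(spans[i], spans[j]) >= identity_threshold:
                parent[find(i)] = find(j)

    clusters: Dict[int, List[int]] = {}
    for i in range(len(usable)):
        clusters.setdefault(find(i), []).append(i)

    def three_prime_key(members: List[int]) -> Tuple:
        # 3′-most member: on the forward strand of a V→J→C translocon the
        # 3′-most V has the largest start coordinate.
        positions = [usable[i].locus[1] for i in members if usable[i].locus is not None]
        if positions and len(positions) == len(members):
            return (0, -max(positions))
        return (1, min(usable[i].id for i in members))

    ordered = sorted(clusters.values(), key=three_prime_key)
    labels: Dict[str, str] = {}
    for rank, members in enumerate(ordered, start=1):
        for i in members:
            labels[usable[i].id] = f"Vg{rank}"
    return labels, excluded
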