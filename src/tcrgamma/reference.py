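"""Synthetic reference germline database and locus builders.

The published chicken TCRγ germline inventory consists of 44 Vγ segments in
six subgroups (6, 19, 9, 4, 3 and 3 members; 28 potentially functional),
three functional Jγ segments and a single Cγ gene.  The nucleotide
sequences themselves are not redistributable here, so this module builds a
**synthetic** database that transcribes the inventory's *structure*: the
same segment ids, subgroup memberships, functionality classes (pseudogenes
carry internal stops, ORFs lack a conserved anchor or an intact RSS) and
germline CDR3 contributions (15, 15, 23 and 13 bp for subgroups Vγ1–Vγ4
when joined to a J head of 6 nt).  Sequences are generated deterministically
from a fixed seed, so the database is identical across runs and platforms.

Also provides a synthetic tandem-duplication locus for exercising the
dot-plot analyzer.
"""

from __future__ import annotations

import re
from typing import Dict, List, Optional, Tuple

import numpy as np

from .germline import (
    J_FGXG_PATTERN,
    RSS_HEPTAMER,
    RSS_NONAMER,
    GermlineDatabase,
    GermlineSegment,
    RSSHit,
)

_REFERENCE_SEED = 20210921

# V-REGION layout (nt, frame 0): FR1 75, CDR1 18, FR2 51, CDR2 24, FR3 114.
_REGIONS = {"FR1": (0, 75), "CDR1": (75, 93), "FR2": (93, 144),
            "CDR2": (144, 168), "FR3": (168, 282)}
_FR3_END = 282
_LEADER_LEN = 45
_C23_CODON = 72      # last codon of FR1
_W41_CODON = 99      # planted Trp codon inside FR2
_ANCHOR_BLOCK = "TACTATTGT"   # FR3 terminus: Tyr-Tyr-Cys ending at C104

# Germline CDR3 V-side tails (after the C104 codon).  T-free by design so
# junctional randomness cannot complete a CDR3 anchor motif inside the tail.
_TAILS = {1: "GCAGGAGCC", 2: "GCCGGAGAC", 3: "GCAGGAGCAGGAGCAGC",
          4: "GCAGGAC", 5: "GGAGCAGCC", 6: "GCAGCAGGC"}

_SUBGROUP_SIZES = {1: 6, 2: 19, 3: 9, 4: 4, 5: 3, 6: 3}
_PSEUDO = {"Vg1.4", "Vg2.7", "Vg2.9", "Vg2.10", "Vg2.11", "Vg3.5", "Vg4.4",
           "Vg5.1", "Vg5.2", "Vg5.3", "Vg6.1", "Vg6.2", "Vg6.3"}
#: ORF segments and the defect planted in each
_ORF_DEFECT = {"Vg1.1": "w41", "Vg1.5": "rss", "Vg2.18": "c23"}

#: per-subgroup substitution count applied to each member relative to the
#: subgroup ancestor; Vγ2 is the diverse subgroup.
_MEMBER_MUTATIONS = {1: 10, 2: 24, 3: 10, 4: 10, 5: 12, 6: 12}

_J_SEGMENTS = {
    "Jg1": "GGGAAC" + "TTTGGCACAGGA" + "AAGCCGACCCTGACCGTCCTGGAG",
    "Jg2": "GGCAAC" + "TTCGGAAGTGGT" + "AAGACCAAGCTGACCGTGGAGCCG",
    "Jg3": "GGGGAC" + "TTTGGAACAGGT" + "ACCAAGGTGGAGCTGAAGCGCGCC",
}

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_V_MOTIF = re.compile(r"TAC[TC]A[TC]TG[TC]")

#: constant 5′ UTR prepended to simulated transcripts (T-free, motif-free)
UTR_SEQ = "GCAGCGGCAGCG"


def _random_codons(rng: np.random.Generator, n_codons: int) -> str:
    """n_codons random non-stop codons."""
    out = []
    while len(out) < n_codons:
        codon = "".join(_BASES[i] for i in rng.integers(0, 4, size=3))
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def _mutate(seq: str, pos: int, rng: np.random.Generator, avoid_stop: bool) -> str:
    """Substitute the base at ``pos``, optionally keeping the frame-0 codon non-stop."""
    old = seq[pos]
    choices = [b for b in _BASES if b != old]
    rng.shuffle(choices)
    for new in choices:
        cand = seq[:pos] + new + seq[pos + 1:]
        if avoid_stop:
            c0 = pos - pos % 3
            if cand[c0 : c0 + 3] in _STOPS:
                continue
        return cand
    return seq


def _scrub_motifs(seq: str, rng: np.random.Generator,
                  allowed_v_anchor: Optional[int] = None,
                  allowed_j_anchor: Optional[int] = None,
                  in_frame: bool = False) -> str:
    """Destroy every CDR3 anchor-motif occurrence except the sanctioned ones.

    Spurious occurrences of the Tyr(Tyr/His)Cys or Phe-Gly-X-Gly nucleotide
    motifs inside germline sequence would derail CDR3 extraction, so the
    builder removes them by point substitution at the motif centre.
    """
    for _ in range(50):
        dirty = False
        for pattern, allowed in ((_V_MOTIF, allowed_v_anchor),
                                 (J_FGXG_PATTERN, allowed_j_anchor)):
            for m in pattern.finditer(seq):
                if allowed is not None and m.start() == allowed:
                    continue
                seq = _mutate(seq, m.start() + 4, rng, avoid_stop=in_frame)
                dirty = True
                break
            if dirty:
                break
        if not dirty:
            return seq
    raise RuntimeError("could not scrub anchor motifs from synthetic sequence")


def _make_ancestor(rng: np.random.Generator, subgroup: int) -> Tuple[str, str]:
    """Leader and V-REGION of one subgroup ancestor, anchors planted."""
    leader = "ATG" + _random_codons(rng, _LEADER_LEN // 3 - 1)
    body = _random_codons(rng, _FR3_END // 3)
    body = body[:_C23_CODON] + "TGT" + body[_C23_CODON + 3:]
    body = body[:_W41_CODON] + "TGG" + body[_W41_CODON + 3:]
    body = body[: _FR3_END - 9] + _ANCHOR_BLOCK
    seq = body + _TAILS[subgroup]
    return leader, seq


def _derive_member(rng: np.random.Generator, leader: str, ancestor: str,
                   n_mut: int) -> str:
    """Mutate the ancestor V-REGION, sparing anchors and the CDR3 tail."""
    protected = set(range(_C23_CODON, _C23_CODON + 3))
    protected |= set(range(_W41_CODON, _W41_CODON + 3))
    protected |= set(range(_FR3_END - 9, len(ancestor)))
    candidates = [p for p in range(len(ancestor)) if p not in protected]
    seq = ancestor
    for pos in rng.choice(candidates, size=n_mut, replace=False):
        seq = _mutate(seq, int(pos), rng, avoid_stop=True)
    return seq


def build_reference_db(seed: int = _REFERENCE_SEED) -> GermlineDatabase:
    """Build the synthetic 44 V / 3 J / 1 C germline database.

    Deterministic: the default seed is fixed, so repeated calls return
    byte-identical sequences.
    """
    rng = np.random.default_rng(seed)
    segments: List[GermlineSegment] = []
    contig = "chr2_syn"
    cursor = 96_000  # 3′-most V start; members are laid out 3′→5′

    v_rss = RSSHit(RSS_HEPTAMER, RSS_NONAMER, 23, 0, 0, _FR3_END + len(_TAILS[1]),
                   "three_prime")
    for sub, size in _SUBGROUP_SIZES.items():
        leader, ancestor = _make_ancestor(rng, sub)
        for member in range(1, size + 1):
            seg_id = f"Vg{sub}.{member}"
            seq = _derive_member(rng, leader, ancestor, _MEMBER_MUTATIONS[sub])
            if seg_id in _PSEUDO:
                # plant two in-frame stops: one in FR1, one in FR3
                seq = seq[:30] + "TAA" + seq[33:]
                seq = seq[:210] + "TGA" + seq[213:]
            defect = _ORF_DEFECT.get(seg_id)
            if defect == "w41":
                seq = seq[:_W41_CODON] + "CGG" + seq[_W41_CODON + 3:]
            elif defect == "c23":
                seq = seq[:_C23_CODON] + "AGT" + seq[_C23_CODON + 3:]
            full = _scrub_motifs(
                leader + seq, rng,
                allowed_v_anchor=len(leader) + _FR3_END - 9,
                in_frame=seg_id not in _PSEUDO,
            )
            leader_f, seq_f = full[:len(leader)], full[len(leader):]
            functionality = ("pseudo" if seg_id in _PSEUDO
                             else "ORF" if seg_id in _ORF_DEFECT else "functional")
            rss = None if defect == "rss" else RSSHit(
                RSS_HEPTAMER, RSS_NONAMER, 23, 0, 0, len(seq_f), "three_prime")
            cursor -= 2_000
            segments.append(GermlineSegment(
                id=seg_id, kind="V", seq_nt=seq_f, functionality=functionality,
                subgroup=f"Vg{sub}", leader_nt=leader_f, regions=dict(_REGIONS),
                rss=rss, locus=(contig, cursor, cursor + len(full), "+"),
            ))

    j_rss = RSSHit(RSS_HEPTAMER, RSS_NONAMER, 12, 0, 0, -7, "five_prime")
    for i, (seg_id, seq) in enumerate(_J_SEGMENTS.items()):
        start = 97_000 + i * 500
        segments.append(GermlineSegment(
            id=seg_id, kind="J", seq_nt=seq, functionality="functional",
            rss=j_rss, locus=(contig, start, start + len(seq), "+"),
        ))

    c_seq = _scrub_motifs(_random_codons(rng, 50), rng, in_frame=True)
    segments.append(GermlineSegment(
        id="Cg", kind="C", seq_nt=c_seq, functionality="functional",
        locus=(contig, 99_000, 99_000 + len(c_seq), "+"),
    ))
    return GermlineDatabase(segments)


# ---------------------------------------------------------------------------
# Synthetic tandem-duplication locus (dot-plot demonstrator)
# ---------------------------------------------------------------------------


def make_tandem_locus(
    unit_len: int = 17_000,
    n_units: int = 4,
    divergence: float = 0.05,
    flank: int = 2_000,
    seed: int = 0,
) -> str:
    """Genomic sequence with ``n_units`` tandem copies of one ancestral unit.

    Each copy carries independent substitutions at rate ``divergence``, so
    pairwise copy identity is roughly ``(1 - divergence)**2`` plus chance
    matches (~0.90 at the default) — comparable to the ≥83 % identity of the
    natural homology units.  Flanking sequence is unrelated random DNA.
    """
    rng = np.random.default_rng(seed)
    unit = "".join(_BASES[i] for i in rng.integers(0, 4, size=unit_len))
    parts = ["".join(_BASES[i] for i in rng.integers(0, 4, size=flank))]
    for _ in range(n_units):
        copy = np.frombuffer(unit.encode(), dtype=np.uint8).copy()
        hit = rng.random(unit_len) < divergence
        shift = rng.integers(1, 4, size=int(hit.sum()))
        idx = {65: 0, 67: 1, 71: 2, 84: 3}
        lut = np.array([ord(b) for b in _BASES], dtype=np.uint8)
        base_idx = np.array([idx[b] for b in copy[hit]])
        copy[hit] = lut[(base_idx + shift) % 4]
        parts.append(copy.tobytes().decode())
    parts.append("".join(_BASES[i] for i in rng.integers(0, 4, size=flank)))
    return "".join(parts)
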