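"""Germline model: loading, anchors, functionality, RSS scan, subgroups."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrgamma import (
    GermlineDatabase,
    GermlineError,
    GermlineSegment,
    alignment_identity,
    classify_functionality,
    cluster_subgroups,
    read_germline_db,
    scan_rss,
    validate_anchor_residues,
    write_germline_db,
)
from tcrgamma.germline import METADATA_COLUMNS, RSS_HEPTAMER, RSS_NONAMER

from conftest import random_dna


def make_v(seq_id: str, seq: str, **kwargs) -> GermlineSegment:
    """Minimal V segment whose FR1..FR3 span covers the whole sequence."""
    regions = {"FR1": (0, 3), "CDR1": (3, 6), "FR2": (6, 9), "CDR2": (9, 12),
               "FR3": (12, len(seq))}
    return GermlineSegment(id=seq_id, kind="V", seq_nt=seq, regions=regions, **kwargs)


# ---------------------------------------------------------------------------
# database round-trip and load errors
# ---------------------------------------------------------------------------


def test_database_roundtrip_through_files(db, tmp_path):
    write_germline_db(db, tmp_path / "g.fasta", tmp_path / "g.tsv")
    reloaded = read_germline_db(tmp_path / "g.fasta", tmp_path / "g.tsv")
    assert len(reloaded) == len(db)
    for seg in db:
        other = reloaded[seg.id]
        assert other.seq_nt == seg.seq_nt
        assert other.leader_nt == seg.leader_nt
        assert other.functionality == seg.functionality
        assert other.subgroup == seg.subgroup
        assert dict(other.regions) == dict(seg.regions)


def test_load_errors_name_the_offending_id(db, tmp_path):
    write_germline_db(db, tmp_path / "g.fasta", tmp_path / "g.tsv")
    fasta = (tmp_path / "g.fasta").read_text()
    (tmp_path / "extra.fasta").write_text(fasta + ">Vg9.9\nACGTACGT\n")
    with pytest.raises(GermlineError, match="Vg9.9"):
        read_germline_db(tmp_path / "extra.fasta", tmp_path / "g.tsv")


def test_empty_database_is_flagged_unusable(tmp_path):
    (tmp_path / "e.fasta").write_text("")
    (tmp_path / "e.tsv").write_text("\t".join(METADATA_COLUMNS) + "\n")
    empty = read_germline_db(tmp_path / "e.fasta", tmp_path / "e.tsv")
    assert len(empty) == 0
    assert not empty.usable_for_pipeline


def test_duplicate_ids_rejected(db):
    seg = db["Jg1"]
    with pytest.raises(GermlineError, match="duplicate"):
        GermlineDatabase([seg, seg])


# ---------------------------------------------------------------------------
# anchors and functionality
# ---------------------------------------------------------------------------


def _codons(n, codon="GCA"):
    return codon * n


def test_anchor_detection_and_mutation():
    # FR1 ends in TGT (Cys), FR2 contains TGG (Trp), FR3 ends TAC TAT TGT
    seq = (_codons(24) + "TGT"            # FR1, C23 at last codon
           + _codons(6)                     # CDR1
           + _codons(8) + "TGG" + _codons(8)  # FR2 with Trp
           + _codons(8)                     # CDR2
           + _codons(35) + "TACTATTGT")     # FR3 ending at C104
    regions = {"FR1": (0, 75), "CDR1": (75, 93), "FR2": (93, 144),
               "CDR2": (144, 168), "FR3": (168, 282)}
    seg = GermlineSegment(id="Vx", kind="V", seq_nt=seq, regions=regions)
    rep = validate_anchor_residues(seg)
    assert rep.all_present and not rep.internal_stop

    mutated = dataclasses.replace(seg, seq_nt=seq[:279] + "TGG")
    rep2 = validate_anchor_residues(mutated)
    assert not rep2.c104_present and rep2.c23_present and rep2.w41_present

    stopped = dataclasses.replace(seg, seq_nt=seq[:30] + "TAA" + seq[33:])
    assert validate_anchor_residues(stopped).internal_stop
    assert classify_functionality(stopped) == "pseudo"


def test_functionality_partitions_reference(db):
    """Recomputed classes match the stored annotation and partition the set."""
    calls = {seg.id: classify_functionality(seg) for seg in db.by_kind("V")}
    assert all(c in ("functional", "ORF", "pseudo") for c in calls.values())
    for seg in db.by_kind("V"):
        assert calls[seg.id] == seg.functionality
    assert classify_functionality(db["Vg1.5"], require_rss=False) == "functional"
    assert classify_functionality(db["Vg1.5"], require_rss=True) == "ORF"


def test_anchor_validation_requires_regions(db):
    bare = dataclasses.replace(db["Vg1.2"], regions={})
    with pytest.raises(GermlineError):
        validate_anchor_residues(bare)


# ---------------------------------------------------------------------------
# RSS scanning
# ---------------------------------------------------------------------------


def brute_force_rss(dna, spacer_len, max_mm):
    span = 7 + spacer_len + 9
    hits = []
    for pos in range(len(dna) - span + 1):
        hm = sum(a != b for a, b in zip(dna[pos:pos + 7], RSS_HEPTAMER))
        nm = sum(a != b for a, b in zip(dna[pos + 7 + spacer_len:pos + span], RSS_NONAMER))
        if hm <= max_mm and nm <= max_mm:
            hits.append((pos, hm, nm))
    return hits


@pytest.mark.parametrize("spacer", [12, 23])
def test_scan_rss_exact_consensus(spacer, rng):
    dna = RSS_HEPTAMER + random_dna(rng, spacer) + RSS_NONAMER
    hits = scan_rss(dna, "five_prime", spacer, max_mismatches=0)
    assert len(hits) == 1
    assert hits[0].position == 0
    assert hits[0].total_mismatches == 0


def test_scan_rss_mismatch_threshold(rng):
    dna = "AACAGTG" + random_dna(rng, 12) + RSS_NONAMER  # 1 heptamer mismatch
    assert scan_rss(dna, "five_prime", 12, max_mismatches=0) == []
    hits = scan_rss(dna, "five_prime", 12, max_mismatches=1)
    assert len(hits) == 1 and hits[0].heptamer_mismatches == 1


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=28, max_size=120),
       st.integers(min_value=0, max_value=3))
def test_scan_rss_equals_exhaustive_scan(dna, max_mm):
    hits = scan_rss(dna, "three_prime", 12, max_mm)
    expected = brute_force_rss(dna, 12, max_mm)
    assert sorted((h.position, h.heptamer_mismatches, h.nonamer_mismatches)
                  for h in hits) == sorted(expected)


def test_scan_rss_too_short_returns_empty():
    assert scan_rss("CACAGTG", "three_prime", 12, 3) == []


# ---------------------------------------------------------------------------
# subgroup clustering
# ---------------------------------------------------------------------------


def test_identical_sequences_cluster_together(rng):
    seq = random_dna(rng, 90)
    a, b = make_v("A", seq), make_v("B", seq)
    labels, _ = cluster_subgroups([a, b])
    assert labels["A"] == labels["B"]


def test_distant_sequences_split(rng):
    a = make_v("A", random_dna(rng, 90))
    b = make_v("B", random_dna(rng, 90))
    # random pairs sit near ~55% global identity, below the 70% criterion
    assert alignment_identity(a.seq_nt, b.seq_nt) < 0.70
    labels, _ = cluster_subgroups([a, b])
    assert labels["A"] != labels["B"]


def test_single_linkage_transitive_closure(rng):
    """Clusters equal the brute-force transitive closure of pairwise identity."""
    seqs = {}
    base = random_dna(rng, 120)
    for i in range(6):
        arr = list(base)
        for pos in rng.choice(120, size=int(rng.integers(10, 50)), replace=False):
            arr[pos] = "ACGT"[int(rng.integers(0, 4))]
        seqs[f"S{i}"] = "".join(arr)
    segs = [make_v(k, v) for k, v in seqs.items()]
    labels, _ = cluster_subgroups(segs)

    ids = sorted(seqs)
    adj = {i: {i} for i in ids}
    for i in ids:
        for j in ids:
            if i < j and alignment_identity(seqs[i], seqs[j]) >= 0.70:
                adj[i].add(j)
                adj[j].add(i)
    # brute-force closure
    def component(start):
        seen, todo = set(), [start]
        while todo:
            x = todo.pop()
            if x in seen:
                continue
            seen.add(x)
            todo.extend(adj[x])
        return frozenset(seen)

    expected = {i: component(i) for i in ids}
    for i in ids:
        for j in ids:
            assert (labels[i] == labels[j]) == (expected[i] == expected[j])


def test_cluster_labels_invariant_under_permutation(db, rng):
    vs = db.by_kind("V")
    perm = [vs[i] for i in rng.permutation(len(vs))]
    labels_a, _ = cluster_subgroups(vs)
    labels_b, _ = cluster_subgroups(perm)
    assert labels_a == labels_b


def test_cluster_excludes_unannotated(db):
    bare = dataclasses.replace(db["Vg1.2"], id="bare", regions={})
    labels, excluded = cluster_subgroups([db["Vg1.3"], bare])
    assert excluded == ["bare"]
    assert "bare" not in labels
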