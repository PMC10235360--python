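"""Probe-design rules, candidate enumeration and the brute-force design oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phdsq.panel import (ARM_LENGTH, GC_MAX, GC_MIN, InvalidSequenceError,
                         NoCandidateError, ProbePanel, TranscriptRecord,
                         design_panel, enumerate_candidate_sites, gc_fraction,
                         homology_screen, make_pair, panel_to_frame,
                         read_panel_tsv, write_panel_tsv)

_BASES = np.array(list("ACGT"))


def _random_seq(n, seed, gc=0.5):
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


# ---------------------------------------------------------------------------
# gc_fraction


@pytest.mark.parametrize("seq,expected", [
    ("GCGC", 1.0),
    ("AAAA", 0.0),
    ("ATGCATGCAT", 0.4),  # 4 G/C of 10, counted by hand
])
def test_gc_fraction_examples(seq, expected):
    assert gc_fraction(seq) == pytest.approx(expected, abs=1e-15)


@pytest.mark.parametrize("bad", ["", "ACGU", "acgt", "ACGN"])
def test_gc_fraction_rejects_invalid(bad):
    with pytest.raises(InvalidSequenceError):
        gc_fraction(bad)


@given(st.text(alphabet="ACGT", min_size=1, max_size=200))
def test_gc_fraction_properties(seq):
    g = gc_fraction(seq)
    assert 0.0 <= g <= 1.0
    # complementing the sequence preserves GC fraction
    comp = seq.translate(str.maketrans("ACGT", "TGCA"))
    assert gc_fraction(comp) == pytest.approx(g)


# ---------------------------------------------------------------------------
# candidate enumeration


def test_minimal_transcript_single_candidate():
    t = TranscriptRecord("G", "G_T1", _random_seq(54, 1))
    sites = enumerate_candidate_sites(t)
    assert [s.junction for s in sites] == [27]
    assert not sites[0].exon_spanning


def test_junction_snp_excluded():
    t = TranscriptRecord("G", "G_T1", _random_seq(54, 1), snp_positions=frozenset({27}))
    assert enumerate_candidate_sites(t) == []


def test_sixty_nt_with_boundary_all_spanning():
    t = TranscriptRecord("G", "G_T1", _random_seq(60, 2), exon_boundaries=(30,))
    sites = enumerate_candidate_sites(t)
    assert [s.junction for s in sites] == list(range(27, 34))
    assert all(s.exon_spanning for s in sites)


def test_short_transcript_raises():
    with pytest.raises(NoCandidateError):
        enumerate_candidate_sites(TranscriptRecord("G", "G_T1", _random_seq(53, 3)))


def test_transcript_invariants_enforced():
    with pytest.raises(ValueError):
        TranscriptRecord("G", "T", _random_seq(60, 4), exon_boundaries=(30, 30))
    with pytest.raises(ValueError):
        TranscriptRecord("G", "T", _random_seq(60, 4), exon_boundaries=(60,))
    with pytest.raises(ValueError):
        TranscriptRecord("G", "T", _random_seq(60, 4), snp_positions=frozenset({99}))


# ---------------------------------------------------------------------------
# homology screen


def _pair_on(t, junction=ARM_LENGTH, probe_id="p1"):
    return make_pair(t, junction, probe_id)


def test_homology_self_match_excluded():
    t = TranscriptRecord("G", "G_T1", _random_seq(80, 5))
    pair = _pair_on(t)
    passed, count = homology_screen(pair, [t])
    # own gene is excluded, leaving an empty background (warned)
    assert passed


def test_homology_exact_offtarget_fails():
    t = TranscriptRecord("G", "G_T1", _random_seq(80, 6))
    pair = _pair_on(t)
    other = TranscriptRecord("H", "H_T1",
                             _random_seq(20, 7) + pair.left.arm_seq + _random_seq(20, 8))
    passed, count = homology_screen(pair, [t, other], k=27)
    assert not passed and count >= 1


def test_homology_short_shared_kmer_passes():
    t = TranscriptRecord("G", "G_T1", _random_seq(80, 9))
    pair = _pair_on(t)
    shared10 = pair.reference[:10]
    other = TranscriptRecord("H", "H_T1", _random_seq(30, 10) + shared10 + _random_seq(30, 11))
    passed, count = homology_screen(pair, [t, other], k=27)
    assert passed and count == 0


def test_homology_empty_background_warns():
    t = TranscriptRecord("G", "G_T1", _random_seq(80, 12))
    with pytest.warns(UserWarning):
        passed, count = homology_screen(_pair_on(t), [])
    assert passed and count == 0


# ---------------------------------------------------------------------------
# design_panel and its exhaustive oracle


def _brute_force_design(transcripts, genes, pairs_per_gene, k=27, max_shared=1):
    """Independent re-derivation: enumerate every junction on every transcript,
    apply the four rules directly, rank by the documented key, take the top."""
    chosen = {}
    for gene in genes:
        cands = []
        for t in sorted((x for x in transcripts if x.gene_id == gene),
                        key=lambda x: x.transcript_id):
            if len(t.seq) < 54:
                continue
            for j in range(27, len(t.seq) - 27 + 1):
                if j in t.snp_positions:
                    continue
                left, right = t.seq[j - 27:j], t.seq[j:j + 27]
                gl = (left.count("G") + left.count("C")) / 27
                gr = (right.count("G") + right.count("C")) / 27
                if not (GC_MIN <= gl <= GC_MAX and GC_MIN <= gr <= GC_MAX):
                    continue
                ref = left + right
                ref_kmers = {ref[i:i + k] for i in range(len(ref) - k + 1)}
                bad = False
                for o in transcripts:
                    if o.gene_id == gene:
                        continue
                    okmers = {o.seq[i:i + k] for i in range(len(o.seq) - k + 1)}
                    if len(ref_kmers & okmers) >= max_shared:
                        bad = True
                        break
                if bad:
                    continue
                spanning = any(j - 27 <= b < j + 27 for b in t.exon_boundaries)
                dl, dr = abs(gl - 0.5), abs(gr - 0.5)
                cands.append(((0 if spanning else 1, round(max(dl, dr), 12),
                               round((dl + dr) / 2, 12), j), j, left, right))
        cands.sort(key=lambda c: c[0])
        picked, seen = [], set()
        for _, j, left, right in cands:
            if j in seen:
                continue
            picked.append((j, left, right))
            seen.add(j)
            if len(picked) == pairs_per_gene:
                break
        chosen[gene] = picked
    return chosen


@pytest.mark.parametrize("pairs_per_gene", [1, 2])
def test_design_matches_brute_force_oracle(pairs_per_gene):
    """On toy transcripts <= 200 nt, the designer must emit exactly the
    top-ranked pairs of an exhaustive enumeration."""
    transcripts = [
        TranscriptRecord("G1", "G1_T1", _random_seq(180, 21), exon_boundaries=(90,),
                         snp_positions=frozenset({40, 120})),
        TranscriptRecord("G2", "G2_T1", _random_seq(150, 22), exon_boundaries=(75,)),
        TranscriptRecord("G3", "G3_T1", _random_seq(200, 23)),
    ]
    genes = ["G1", "G2", "G3"]
    res = design_panel(transcripts, genes, pairs_per_gene)
    oracle = _brute_force_design(transcripts, genes, pairs_per_gene)
    got = {}
    for p in res.panel:
        got.setdefault(p.gene_id, []).append((p.junction_pos, p.left.arm_seq,
                                              p.right.arm_seq))
    assert got == {g: v for g, v in oracle.items() if v}


def test_designed_pairs_satisfy_all_rules(panel):
    """Every emitted pair: 27-nt arms, per-arm GC in band, contiguous arms,
    no SNP at the junction, unique 54-mer references."""
    transcripts = {t.gene_id: t for t in
                   __import__("phdsq.datasets", fromlist=["x"]).synthetic_transcriptome()}
    refs = set()
    for p in panel:
        assert len(p.left.arm_seq) == len(p.right.arm_seq) == 27
        assert GC_MIN <= gc_fraction(p.left.arm_seq) <= GC_MAX
        assert GC_MIN <= gc_fraction(p.right.arm_seq) <= GC_MAX
        t = transcripts[p.gene_id]
        assert t.seq[p.junction_pos - 27:p.junction_pos + 27] == p.reference
        assert p.junction_pos not in t.snp_positions
        refs.add(p.reference)
    assert len(refs) == len(panel)


def test_design_is_deterministic():
    transcripts = [TranscriptRecord("G1", "G1_T1", _random_seq(120, 31)),
                   TranscriptRecord("G2", "G2_T1", _random_seq(120, 32))]
    a = panel_to_frame(design_panel(transcripts, ["G1", "G2"], 1).panel)
    b = panel_to_frame(design_panel(transcripts, ["G1", "G2"], 1).panel)
    assert a.equals(b)


def test_unsatisfiable_gene_lands_in_failure_list():
    transcripts = [TranscriptRecord("POLYA", "POLYA_T1", "A" * 100)]
    res = design_panel(transcripts, ["POLYA", "MISSING"], 1)
    assert len(res.panel) == 0
    assert {f.gene_id for f in res.failures} == {"POLYA", "MISSING"}


def test_two_pairs_have_distinct_junctions():
    t = TranscriptRecord("G", "G_T1", _random_seq(200, 33))
    res = design_panel([t], ["G"], pairs_per_gene=2)
    assert len(res.panel) == 2
    j = [p.junction_pos for p in res.panel]
    assert j[0] != j[1]


def test_panel_tsv_round_trip(tmp_path, panel):
    path = tmp_path / "panel.tsv"
    write_panel_tsv(panel, path)
    back = read_panel_tsv(path)
    assert panel_to_frame(back).equals(panel_to_frame(panel))
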