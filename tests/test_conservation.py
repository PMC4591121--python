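"""Cross-species conservation scanning and the substitution-rate contrast."""

import numpy as np
import pytest

from sigma54 import conservation as cons
from sigma54 import io as gio
from sigma54 import motif as mot
from sigma54 import simulate as sim
from sigma54.conservation import SubstitutionTally
from sigma54.io import AnchorRecord, GenomeRecord, reverse_complement

from conftest import truth_site_records


@pytest.fixture(scope="module")
def identity_setup(small_sim, small_sim_records):
    orth, anchors = sim.mutate_ortholog(small_sim["genome"], small_sim["truth"], 0.0, seed=17)
    return orth, anchors


def test_identity_ortholog_scores_match_own(identity_setup, small_sim_records, pssm):
    orth, anchors = identity_setup
    for site, anchor in zip(small_sim_records[:10], anchors[:10]):
        cell = cons.conservation_scan(site, orth, anchor, pssm)
        own = mot.score_sequence(pssm, site.motif)
        assert cell.exact_score == pytest.approx(own)
        assert cell.best_score == pytest.approx(own)
        assert cell.best_offset == 0
        assert cell.exact_sequence == site.motif


def test_best_score_never_below_exact(small_sim, small_sim_records, pssm):
    orth, anchors = sim.mutate_ortholog(small_sim["genome"], small_sim["truth"], 0.15, seed=23)
    for site, anchor in zip(small_sim_records, anchors):
        cell = cons.conservation_scan(site, orth, anchor, pssm)
        assert cell.best_score >= cell.exact_score - 1e-12
        assert abs(cell.best_offset) <= 100


@pytest.mark.parametrize("shift", [-100, -37, 37, 100])
def test_shifted_motif_recovered_exactly(identity_setup, small_sim_records, pssm, shift):
    orth, anchors = identity_setup
    site = small_sim_records[3]
    anchor = next(a for a in anchors if a.site_id == site.site_id)
    seq = list(orth.sequence)
    top = site.motif if site.motif_strand == "+" else reverse_complement(site.motif)
    # erase the original site, re-plant it displaced by `shift`
    for k in range(17):
        seq[site.motif_center - 9 + k] = "A"
    for k in range(17):
        seq[site.motif_center + shift - 9 + k] = top[k]
    shifted = GenomeRecord(orth.id, "".join(seq))
    cell = cons.conservation_scan(site, shifted, anchor, pssm)
    assert cell.best_offset == shift
    assert cell.best_score == pytest.approx(mot.score_sequence(pssm, site.motif))


def test_missing_anchor_gives_empty_cell(small_sim_records, pssm, small_sim):
    site = small_sim_records[0]
    absent = AnchorRecord(site.site_id, "spX", None)
    cell = cons.conservation_scan(site, small_sim["genome"], absent, pssm)
    assert not cell.homolog_found
    assert cell.exact_score is None and cell.best_score is None


def test_best_score_monotone_in_window(small_sim, small_sim_records, pssm):
    orth, anchors = sim.mutate_ortholog(small_sim["genome"], small_sim["truth"], 0.2, seed=31)
    for site, anchor in zip(small_sim_records[:15], anchors[:15]):
        narrow = cons.conservation_scan(site, orth, anchor, pssm, window=20)
        wide = cons.conservation_scan(site, orth, anchor, pssm, window=100)
        assert wide.best_score >= narrow.best_score - 1e-12


# ---------------------------------------------------------------------------
# substitution statistics
# ---------------------------------------------------------------------------


def _cell(site_id, seq, score=20.0, offset=0):
    return cons.ConservationCell(
        site_id=site_id, species="sp", exact_score=score, best_score=score,
        best_offset=offset, best_strand="+", homolog_found=True, exact_sequence=seq,
    )


def test_identical_pair_counts_all_positions(pssm):
    eco = pssm.consensus  # matches consensus everywhere by construction
    tally = cons.substitution_stats({"s1": eco}, [_cell("s1", eco)], pssm)
    assert tally.important_substitutions == 0
    assert tally.important_examined == 5
    assert tally.unimportant_substitutions == 0
    assert tally.unimportant_examined == 5


def test_differences_at_unimportant_positions_only(pssm):
    eco = pssm.consensus
    hom = list(eco)
    for p in (8, 9):  # 1-based unimportant positions
        hom[p - 1] = "A" if eco[p - 1] != "A" else "C"
    tally = cons.substitution_stats({"s1": eco}, [_cell("s1", "".join(hom))], pssm)
    assert tally.important_substitutions == 0
    assert tally.important_examined == 5
    assert tally.unimportant_substitutions == 2
    assert tally.unimportant_examined == 5


def test_consensus_mismatch_excludes_important_position(pssm):
    """A site deviating from the consensus at position 16 contributes only
    4 examined important positions."""
    eco = list(pssm.consensus)
    eco[15] = "A" if pssm.consensus[15] != "A" else "G"
    eco = "".join(eco)
    tally = cons.substitution_stats({"s1": eco}, [_cell("s1", eco)], pssm)
    assert tally.important_examined == 4
    assert tally.unimportant_examined == 5


def test_low_score_and_shifted_pairs_excluded(pssm):
    eco = pssm.consensus
    cells = [
        _cell("s1", eco, score=5.0),  # below min_score 6
        _cell("s1", eco, offset=10),  # not perfectly aligned
    ]
    tally = cons.substitution_stats({"s1": eco}, cells, pssm)
    assert tally.n_pairs == 0


def test_hamming_symmetry(pssm):
    rng = np.random.default_rng(3)
    a = "".join("ACGT"[i] for i in rng.integers(0, 4, 17))
    b = "".join("ACGT"[i] for i in rng.integers(0, 4, 17))
    t_ab = cons.substitution_stats({"s": a}, [_cell("s", b)], pssm, min_score=-1e9)
    t_ba = cons.substitution_stats({"s": b}, [_cell("s", a)], pssm, min_score=-1e9)
    assert t_ab.unimportant_substitutions == t_ba.unimportant_substitutions


def test_fold_ratio_published_tallies():
    tally = SubstitutionTally(35, 1603, 309, 1640)
    assert round(cons.fold_ratio(tally), 1) == 8.6


def test_fold_ratio_equal_rates_is_one():
    assert cons.fold_ratio(SubstitutionTally(10, 100, 10, 100)) == pytest.approx(1.0)


def test_fold_ratio_arithmetic():
    assert cons.fold_ratio(SubstitutionTally(1, 100, 10, 100)) == pytest.approx(10.0)


def test_fold_ratio_zero_important_is_inf():
    assert np.isinf(cons.fold_ratio(SubstitutionTally(0, 100, 5, 100)))


def test_strong_site_threshold_separates_real_from_random(fixture_sites, pssm):
    """The score-6 cutoff for 'strong' homolog sites keeps every genuine
    E. coli site while admitting only ~0.1% of random 17-mers."""
    scores = [mot.score_sequence(pssm, s.motif) for s in fixture_sites]
    assert min(scores) > 6.0
    rng = np.random.default_rng(77)
    rand = [mot.score_sequence(pssm, "".join("ACGT"[i] for i in rng.integers(0, 4, 17)))
            for _ in range(10_000)]
    assert np.mean(np.array(rand) > 6.0) <= 0.0025


def test_constrained_simulation_recovers_high_fold_ratio(small_sim, small_sim_records, pssm):
    """With the strongly constrained motif columns mutating at a tenth of the
    neutral rate, the recovered rate contrast is well above 3."""
    ecoli = {t.site_id: t.sequence for t in small_sim["truth"]}
    cells = []
    for k in range(5):
        orth, anchors = sim.mutate_ortholog(
            small_sim["genome"], small_sim["truth"], 0.10,
            constrained_positions=frozenset({3, 4, 14, 15, 16}),
            seed=400 + k, species=f"sp{k}")
        cells += [cons.conservation_scan(s, orth, a, pssm)
                  for s, a in zip(small_sim_records, anchors)]
    tally = cons.substitution_stats(ecoli, cells, pssm)
    assert tally.n_pairs >= 50
    assert cons.fold_ratio(tally) > 3.0


# ---------------------------------------------------------------------------
# matrix
# ---------------------------------------------------------------------------


def test_matrix_empty_without_species(small_sim_records, pssm):
    m = cons.build_matrix(small_sim_records, {}, [], pssm)
    assert m.shape == (len(small_sim_records), 0)


def test_matrix_identity_column_equals_own_scores(small_sim, small_sim_records, pssm):
    orth, anchors = sim.mutate_ortholog(small_sim["genome"], small_sim["truth"], 0.0, seed=2,
                                        species="self")
    m = cons.build_matrix(small_sim_records, {"self": orth}, anchors, pssm)
    for site in small_sim_records:
        assert m.loc[site.site_id, "self"] == pytest.approx(
            mot.score_sequence(pssm, site.motif))


def test_matrix_rows_ordered_by_class(small_sim_records, pssm):
    m = cons.build_matrix(small_sim_records, {}, [], pssm)
    order = {"OS": 0, "OA": 1, "IS": 2, "IA": 3}
    ranks = [order[sid[:2]] for sid in m.index]
    assert ranks == sorted(ranks)


def test_matrix_mean_score_decays_with_divergence(small_sim, small_sim_records, pssm):
    genomes, anchors = {}, []
    for d in (0.0, 0.05, 0.2):
        orth, a = sim.mutate_ortholog(
            small_sim["genome"], small_sim["truth"], d,
            constrained_positions=frozenset({3, 4, 14, 15, 16}),
            seed=int(d * 100) + 50, species=f"d{d}")
        genomes[f"d{d}"] = orth
        anchors += a
    m = cons.build_matrix(small_sim_records, genomes, anchors, pssm)
    means = m.mean(axis=0)
    assert means["d0.0"] >= means["d0.05"] >= means["d0.2"]


def test_duplicate_anchor_rejected(small_sim, small_sim_records, pssm):
    orth, anchors = sim.mutate_ortholog(small_sim["genome"], small_sim["truth"], 0.0, seed=2,
                                        species="x")
    with pytest.raises(ValueError):
        cons.build_matrix(small_sim_records, {"x": orth}, anchors + anchors[:1], pssm)


# ---------------------------------------------------------------------------
# naive anchoring
# ---------------------------------------------------------------------------


def test_anchor_identity_genome_exact(small_sim, small_sim_records):
    site = small_sim_records[0]
    a = cons.anchor_from_alignment(site, small_sim["genome"], small_sim["genome"])
    assert a.found
    assert a.mapped_position == site.motif_center
    assert a.match_fraction == pytest.approx(1.0)


def test_anchor_recovers_diverged_coordinates(small_sim, small_sim_records):
    orth, _ = sim.mutate_ortholog(small_sim["genome"], small_sim["truth"], 0.05, seed=42)
    hits = 0
    for site in small_sim_records:
        a = cons.anchor_from_alignment(site, small_sim["genome"], orth)
        if a.found and abs(a.mapped_position - site.motif_center) <= 2:
            hits += 1
    assert hits / len(small_sim_records) >= 0.95


def test_anchor_missing_on_scrambled_genome(small_sim, small_sim_records):
    rng = np.random.default_rng(0)
    scrambled = GenomeRecord("s", "".join("ACGT"[i] for i in rng.integers(0, 4, 50_000)))
    a = cons.anchor_from_alignment(small_sim_records[0], small_sim["genome"], scrambled)
    assert not a.found
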