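"""Nascent-chain categorization and chaperone binding models."""

import dataclasses

import numpy as np
import pytest

from chapbind.binding import (
    CAT_I,
    CAT_II,
    CAT_III,
    ModelParams,
    categorize,
    dnak_raw,
    folded_region_mask,
    molten_globule_raw,
    nascent_state,
    normalize_profile,
    predict_gene,
    structured_fraction,
    tf_raw,
)
from chapbind.contacts import (
    ContactMap,
    DomainAnnotation,
    DomainCandidate,
    ResidueContact,
    assign_domains,
    extract_contacts,
    label_contact_domains,
)
from chapbind.synthetic import SyntheticProteinSpec, make_structure

INTRA, INTER, UNASSIGNED = "intra", "inter", "unassigned"


def naive_scores(cmap, params):
    """Independent per-L re-scan of every contact with plain Python.

    Returns (tf, dnak, mg, structured_fraction) arrays of length N.
    Deliberately naive: sets, dicts and explicit loops only.
    """
    N = cmap.n_residues
    contacts = [(c.i, c.j, c.strength, c.domain_label) for c in cmap.contacts]
    tf = np.zeros(N)
    dk = np.zeros(N)
    sf = np.zeros(N)
    for L in range(1, N + 1):
        emerged = set(range(1, max(0, L - params.tunnel_len) + 1))
        s_r = {}
        in_iii = set()
        for i, j, s, _ in contacts:
            if i in emerged and j in emerged:
                s_r[i] = s_r.get(i, 0) + s
                s_r[j] = s_r.get(j, 0) + s
                in_iii.update((i, j))
        cum = 0.0
        eligible = set()
        for r in range(L, 0, -1):
            v = s_r.get(r, 0)
            cum += v if v >= params.res_strength_min else 0
            if cum > params.cum_threshold:
                eligible.add(r)
        for i, j, s, lab in contacts:
            if lab == INTRA and i in emerged and j not in emerged and i in eligible:
                tf[L - 1] += s
            if lab == INTER and i in emerged and i in eligible:
                dk[L - 1] += s
        if emerged:
            sf[L - 1] = len(in_iii & emerged) / len(emerged)
    return tf, dk, sf


def _toy_map():
    """Hand-built two-domain protein, N=100, D1=[1,40], D2=[51,90]."""
    contacts = [
        ResidueContact(5, 20, 800, INTRA),
        ResidueContact(10, 30, 400, INTRA),
        ResidueContact(20, 35, 100, INTRA),
        ResidueContact(20, 60, 120, INTER),
        ResidueContact(55, 85, 800, INTRA),
        ResidueContact(2, 45, 50, UNASSIGNED),
    ]
    cmap = ContactMap("toy", 100, contacts)
    ann = DomainAnnotation(
        "toy", [DomainCandidate(1, 40, 1, "D1"), DomainCandidate(51, 90, 2, "D2")]
    )
    return cmap, ann


class TestNascentState:
    def test_tunnel_boundaries(self):
        s = nascent_state(30, 200)
        assert s.emerged == frozenset() and s.tunnel == frozenset(range(1, 31))
        assert nascent_state(31, 200).emerged == frozenset({1})
        s = nascent_state(100, 200)
        assert s.emerged == frozenset(range(1, 71))
        assert s.emerged | s.tunnel == frozenset(range(1, 101))
        assert not s.emerged & s.tunnel

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            nascent_state(0, 10)
        with pytest.raises(ValueError):
            nascent_state(11, 10)


class TestCategorize:
    @pytest.mark.parametrize(
        "L,expected", [(20, CAT_I), (45, CAT_II), (75, CAT_III)]
    )
    def test_contact_5_40_progression(self, L, expected):
        cmap = ContactMap("p", 100, [ResidueContact(5, 40, 10)])
        cat = categorize(cmap, nascent_state(L, 100))
        assert cat[0] == expected

    def test_random_maps_match_rule_oracle(self, rng):
        """Vectorized categories equal direct per-contact evaluation."""
        for _ in range(10):
            N = int(rng.integers(40, 120))
            pairs = set()
            while len(pairs) < 30:
                i = int(rng.integers(1, N - 6))
                j = int(rng.integers(i + 6, N + 1))
                pairs.add((i, j))
            cmap = ContactMap("r", N, [ResidueContact(i, j, 5) for i, j in sorted(pairs)])
            for L in range(1, N + 1):
                st = nascent_state(L, N)
                cat = categorize(cmap, st)
                for k, c in enumerate(cmap.contacts):
                    em = lambda r: r <= max(0, L - 30)
                    if em(c.i) and em(c.j):
                        assert cat[k] == CAT_III
                    elif em(c.i):
                        assert cat[k] == CAT_II
                    else:
                        assert cat[k] == CAT_I

    def test_partition_and_monotone_progression(self, rng):
        """Every contact has exactly one category at every L, and the
        category index never decreases as translation proceeds."""
        N = 90
        cmap = ContactMap(
            "r", N,
            [ResidueContact(int(i), int(j), 3)
             for i, j in {(int(a), int(a + 6 + b)) for a, b in
                          zip(rng.integers(1, 80, 40), rng.integers(0, 10, 40))
                          if a + 6 + b <= N}],
        )
        prev = None
        for L in range(1, N + 1):
            cat = categorize(cmap, nascent_state(L, N))
            assert np.all((cat >= CAT_I) & (cat <= CAT_III))
            if prev is not None:
                assert np.all(cat >= prev)
            prev = cat


class TestFoldedRegionMask:
    def test_single_strong_residue_pair(self):
        """III strength 800 on residues k and its partner makes everything
        N-terminal of the more C-terminal partner eligible."""
        cmap = ContactMap("p", 100, [ResidueContact(5, 20, 800)])
        elig = folded_region_mask(cmap, nascent_state(60, 100))
        # cumulative from L down: 1600 through residue 5, 800 through 20
        assert list(np.flatnonzero(elig)) == list(range(1, 21))

    def test_weak_residues_ignored(self):
        """Per-residue III strengths below 20 contribute nothing."""
        cmap = ContactMap(
            "p", 100, [ResidueContact(i, i + 10, 19) for i in range(1, 40, 2)]
        )
        elig = folded_region_mask(cmap, nascent_state(100, 100))
        assert not elig.any()

    def test_empty_map_all_ineligible(self):
        cmap = ContactMap("p", 50, [])
        assert not folded_region_mask(cmap, nascent_state(50, 50)).any()


class TestRawScores:
    def test_no_emergence_scores_zero(self):
        cmap, ann = _toy_map()
        for L in (1, 15, 30):
            assert tf_raw(cmap, ann, L) == 0.0
            assert dnak_raw(cmap, ann, L) == 0.0
            assert molten_globule_raw(cmap, ann, L) == 0.0

    def test_hand_computed_tf_and_dnak(self):
        """Frozen hand-summed values for the two-domain toy."""
        cmap, ann = _toy_map()
        # L=50: emerged 1..20; (5,20) is III (s_5=s_20=800, cum>750 for
        # r<=20); II intra: (10,30)+(20,35) = 500, both i eligible
        assert tf_raw(cmap, ann, 50) == 500.0
        assert dnak_raw(cmap, ann, 50) == 120.0  # (20,60), i=20 eligible
        # L=70: emerged 1..40; all D1 contacts III; no II intra left
        assert tf_raw(cmap, ann, 70) == 0.0
        assert dnak_raw(cmap, ann, 70) == 120.0
        # L=95: (55,85) is II intra but residue 55 is not eligible
        assert tf_raw(cmap, ann, 95) == 0.0

    def test_interface_held_unsatisfied_to_termination(self):
        """Inter-domain contacts never become satisfied (DnaK model)."""
        cmap, ann = _toy_map()
        assert dnak_raw(cmap, ann, 100) == 120.0

    def test_single_domain_dnak_zero_everywhere(self):
        contacts = [ResidueContact(5, 20, 800), ResidueContact(10, 40, 900)]
        cmap = ContactMap("s", 80, contacts)
        ann = assign_domains([DomainCandidate(1, 80, 1, "D1")], 80, "s")
        for L in range(1, 81):
            assert dnak_raw(cmap, ann, L) == 0.0

    def test_unassigned_contacts_feed_neither_model(self):
        cmap = ContactMap("u", 100, [ResidueContact(2, 45, 5000, UNASSIGNED)])
        ann = DomainAnnotation("u", [DomainCandidate(1, 40, 1, "D1")])
        for L in (60, 80, 100):
            assert tf_raw(cmap, ann, L) == 0.0
            assert dnak_raw(cmap, ann, L) == 0.0

    def test_monotone_gating(self):
        """Raising the folding-gate thresholds never raises a score."""
        cmap, ann = _toy_map()
        base = ModelParams()
        for L in range(1, 101):
            for tighter in (
                dataclasses.replace(base, res_strength_min=900.0),
                dataclasses.replace(base, cum_threshold=2000.0),
            ):
                assert tf_raw(cmap, ann, L, tighter) <= tf_raw(cmap, ann, L, base)
                assert dnak_raw(cmap, ann, L, tighter) <= dnak_raw(cmap, ann, L, base)

    def test_scores_bounded_by_total_strength(self):
        cmap, ann = _toy_map()
        total = cmap.total_strength()
        for L in range(1, 101):
            assert tf_raw(cmap, ann, L) <= total
            assert dnak_raw(cmap, ann, L) <= total


class TestMoltenGlobule:
    def test_domain_completion_satisfies_immediately(self):
        """A single domain [1..80] scores 0 once all 80 residues attach."""
        cmap = ContactMap("m", 100, [ResidueContact(5, 20, 30), ResidueContact(40, 60, 30)])
        ann = DomainAnnotation("m", [DomainCandidate(1, 80, 1, "D")])
        assert molten_globule_raw(cmap, ann, 79) > 0.0
        for L in (80, 90, 100):
            assert molten_globule_raw(cmap, ann, L) == 0.0

    def test_hand_summed_partial_domain(self):
        """At L=60 the emerged residues 1..30 contribute their full native
        contact strengths."""
        cmap = ContactMap(
            "m", 100,
            [ResidueContact(5, 20, 30), ResidueContact(10, 70, 45),
             ResidueContact(40, 60, 30)],
        )
        ann = DomainAnnotation("m", [DomainCandidate(1, 80, 1, "D")])
        # residues 1..30: 5 (30), 20 (30), 10 (45) -> 105
        assert molten_globule_raw(cmap, ann, 60) == 105.0


class TestStructuredFraction:
    def test_no_emerged_is_zero(self):
        cmap = ContactMap("s", 100, [ResidueContact(5, 20, 10)])
        assert structured_fraction(cmap, 30) == 0.0

    def test_fraction_counts_category_iii_residues(self):
        """7 of 10 emerged residues in III contacts -> 0.7."""
        contacts = [
            ResidueContact(1, 7, 5), ResidueContact(2, 8, 5),
            ResidueContact(3, 9, 5), ResidueContact(4, 20, 5),  # II at L=40
        ]
        cmap = ContactMap("s", 100, contacts)
        # L=40: emerged 1..10; III residues {1,2,3,7,8,9} = 6 -> wait 0.6
        assert structured_fraction(cmap, 40) == pytest.approx(0.6)
        contacts.append(ResidueContact(4, 10, 5))
        cmap = ContactMap("s", 100, contacts)
        # now {1,2,3,4,7,8,9,10} = 8 of 10
        assert structured_fraction(cmap, 40) == pytest.approx(0.8)


class TestNormalizeProfile:
    def test_affine_map(self):
        out = normalize_profile(np.array([0.0, 10.0, 5.0]), 2.25)
        assert np.allclose(out, [0.25, 2.25, 1.25])

    def test_constant_profile_floors(self):
        assert np.allclose(normalize_profile(np.zeros(5), 3.0), 0.25)

    def test_max_maps_to_engagement_score(self, rng):
        raw = rng.uniform(0, 50, size=30)
        out = normalize_profile(raw, 4.2)
        assert out[np.argmax(raw)] == pytest.approx(4.2)
        assert out[np.argmin(raw)] == pytest.approx(0.25)

    def test_empty_and_nonpositive_score_rejected(self):
        with pytest.raises(ValueError):
            normalize_profile(np.array([]), 1.0)
        with pytest.raises(ValueError):
            normalize_profile(np.ones(3), 0.0)


class TestPredictGene:
    def test_short_protein_all_zero(self):
        spec = SyntheticProteinSpec(
            n_domains=1, residues_per_domain=25, interface_strength=0.0, seed=2
        )
        model, pae, cands = make_structure(spec)
        pred = predict_gene(model, pae, cands)
        assert not pred.tf.raw.any() and not pred.dnak.raw.any()

    @pytest.mark.parametrize("seed,n_domains", [(3, 1), (4, 2), (5, 2)])
    def test_matches_naive_per_length_rescan(self, seed, n_domains):
        """Full pipeline equals an independent naive re-scan of every
        contact at every nascent length (relaxed gate so it is active)."""
        spec = SyntheticProteinSpec(
            n_domains=n_domains, residues_per_domain=22, linker_len=6,
            interface_strength=40.0, atoms_per_residue=4, seed=seed,
        )
        model, pae, cands = make_structure(spec)
        mp = ModelParams(res_strength_min=10.0, cum_threshold=100.0)
        pred = predict_gene(model, pae, cands, model_params=mp)
        cmap = label_contact_domains(
            extract_contacts(model, pae),
            assign_domains(cands, model.n_residues, model.protein_id),
        )
        tf, dk, sf = naive_scores(cmap, mp)
        assert np.array_equal(pred.tf.raw, tf)
        assert np.array_equal(pred.dnak.raw, dk)
        assert np.allclose(pred.structured_fraction, sf)

    def test_pipeline_equals_manual_composition(self):
        spec = SyntheticProteinSpec(seed=6)
        model, pae, cands = make_structure(spec)
        pred = predict_gene(model, pae, cands)
        cmap = label_contact_domains(
            extract_contacts(model, pae),
            assign_domains(cands, model.n_residues, model.protein_id),
        )
        ann = assign_domains(cands, model.n_residues, model.protein_id)
        for L in (40, 80, 120):
            assert pred.tf.raw[L - 1] == tf_raw(cmap, ann, L)
            assert pred.dnak.raw[L - 1] == dnak_raw(cmap, ann, L)

    def test_planted_two_domain_shape(self):
        """TF signal rises during domain-1 emergence and decays after its
        completion; DnaK holds its interface signal to termination."""
        spec = SyntheticProteinSpec(seed=7)
        model, pae, cands = make_structure(spec)
        pred = predict_gene(model, pae, cands)
        d1_end = cands[0].end
        assert pred.tf.raw[: d1_end + 30].max() > 0
        assert pred.dnak.raw[-1] > 0
        # interface contacts stay unsatisfied: DnaK non-decreasing after
        # the interface has fully emerged and folding gates opened
        tail = pred.dnak.raw[np.argmax(pred.dnak.raw > 0) :]
        assert tail.size and tail[-1] >= tail[0]
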