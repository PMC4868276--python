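"""Sequence-derived encoders against closed forms and brute-force oracles."""

import math
import random

import pytest

from acetylsite.errors import ContractError
from acetylsite.records import AMINO_ACIDS, ProteinRecord, extract_window
from acetylsite.seq_features import (
    KnnReference,
    ebgw_prefix_lengths,
    encode_aaindex,
    encode_acc,
    encode_cksaap,
    encode_ebgw,
    encode_knn,
    encode_lc,
    encode_pc_pseaac,
    encode_pwaa,
)
from acetylsite.tables import atchley_factors, default_averaged_tables, pseaac_scales

from conftest import window_from


def random_window(rng, L=6, pid="r", pos=None):
    length = rng.randint(2 * L + 1, 3 * L + 5)
    seq = "".join(rng.choice(AMINO_ACIDS) for _ in range(length))
    center = pos if pos is not None else rng.randint(1, length)
    return extract_window(ProteinRecord(pid, seq), center, L)


class TestLC:
    @pytest.mark.parametrize(
        "seq,center,expected",
        [
            ("MKKAAAAAAAAAA", 2, (1, 0, 0)),  # N-terminal
            ("AAAAAAKAAAAAA", 7, (0, 1, 0)),  # middle
            ("AAAAAAAAAAAKA", 12, (0, 0, 1)),  # C-terminal
        ],
    )
    def test_one_hot_by_terminal_class(self, seq, center, expected):
        vals = tuple(encode_lc(window_from(seq, center)).values())
        assert vals == expected


class TestPWAA:
    def test_absent_amino_acid_is_zero(self):
        w = window_from("AAAAAAKAAAAAA", 7)
        assert encode_pwaa(w)["PWAA.W"] == 0.0

    def test_homopolymer_closed_form(self):
        # sum_j (j + |j|/L) = L + 1, so C = 1/L for a full homopolymer window
        L = 6
        w = window_from("K" * 13, 7, L=L)
        assert encode_pwaa(w)["PWAA.K"] == pytest.approx(1 / L, abs=1e-12)

    def test_single_occurrence_at_minus_L(self):
        L = 6
        seq = "W" + "A" * 12  # W at offset -L from centre 7
        w = window_from(seq, 7, L=L)
        assert encode_pwaa(w)["PWAA.W"] == pytest.approx(
            (-L + abs(-L) / L) / (L * (L + 1))
        )

    def test_matches_brute_force_on_random_windows(self):
        rng = random.Random(42)
        for _ in range(25):
            w = random_window(rng)
            L = w.radius
            got = encode_pwaa(w)
            for aa in AMINO_ACIDS:
                expected = sum(
                    (j + abs(j) / L) / (L * (L + 1))
                    for j in range(-L, L + 1)
                    if w.valid_mask[j + L] and w.residue_at(j) == aa
                )
                assert got[f"PWAA.{aa}"] == pytest.approx(expected, abs=1e-12)

    def test_weight_sum_bound(self):
        # the largest attainable |C_i| is for an amino acid filling all
        # downstream slots: sum_{j=1..L}(j + j/L) = (L+1)^2/2, normalized
        rng = random.Random(7)
        for _ in range(25):
            w = random_window(rng)
            L = w.radius
            bound = (L + 1) / (2 * L)
            assert all(abs(v) <= bound + 1e-12 for v in encode_pwaa(w).values())


class TestEBGW:
    def test_prefix_lengths_n13_k5(self):
        assert ebgw_prefix_lengths(13, 5) == [3, 5, 8, 10, 13]

    def test_all_hydrophobic_window_is_all_ones(self):
        w = window_from("A" * 13, 7)
        assert set(encode_ebgw(w).values()) == {1.0}

    def test_all_negative_window_projections(self):
        # D is in the negatively-charged group: zero in H1 (hydrophobic|polar)
        # and H2 (hydrophobic|positive), one in H3 (hydrophobic|negative)
        w = window_from("D" * 13, 7)
        feats = encode_ebgw(w)
        for h, expected in ((1, 0.0), (2, 0.0), (3, 1.0)):
            assert all(v == expected for k, v in feats.items() if k.startswith(f"EBGW.h{h}."))

    def test_feature_count_and_range(self):
        rng = random.Random(1)
        for _ in range(20):
            w = random_window(rng)
            feats = encode_ebgw(w, K=5)
            assert len(feats) == 15
            assert all(0.0 <= v <= 1.0 for v in feats.values())

    def test_prefix_counts_monotone(self):
        rng = random.Random(2)
        for _ in range(20):
            w = random_window(rng)
            feats = encode_ebgw(w, K=5)
            lengths = ebgw_prefix_lengths(len(w), 5)
            for h in (1, 2, 3):
                counts = [
                    feats[f"EBGW.h{h}.k{k}"] * lengths[k - 1] for k in range(1, 6)
                ]
                assert all(a <= b + 1e-9 for a, b in zip(counts, counts[1:]))


class TestCKSAAP:
    def test_homopolymer_pairs(self):
        w = window_from("AAAA", 2, L=1)  # window "AAA", 2 adjacent pairs... use full
        w = extract_window(ProteinRecord("p", "AAAA"), 2, 1)
        feats = encode_cksaap(w, k=0)
        # window = AAA: two adjacent AA pairs, but pad at termini? none here
        assert feats["CKSAAP.k0.AA"] == 1.0
        assert sum(feats.values()) == pytest.approx(1.0)

    def test_alternating_pairs_enumerated_by_hand(self):
        w = extract_window(ProteinRecord("p", "AKAK"), 2, 1)
        # window "AKA": pairs AK, KA -> 1/2 each
        feats = encode_cksaap(w, k=0)
        assert feats["CKSAAP.k0.AK"] == pytest.approx(0.5)
        assert feats["CKSAAP.k0.KA"] == pytest.approx(0.5)

    def test_always_400_features(self):
        rng = random.Random(3)
        for _ in range(10):
            feats = encode_cksaap(random_window(rng), k=0)
            assert len(feats) == 400

    def test_sums_to_one_with_valid_pairs(self):
        rng = random.Random(4)
        for _ in range(20):
            feats = encode_cksaap(random_window(rng), k=0)
            vals = list(feats.values())
            assert sum(vals) == pytest.approx(1.0)
            assert all(0.0 <= v <= 1.0 for v in vals)

    def test_gap_padded_positions_excluded(self):
        w = extract_window(ProteinRecord("p", "AK"), 1, 6)
        feats = encode_cksaap(w, k=0)
        assert feats["CKSAAP.k0.AK"] == 1.0  # the only valid pair

    def test_spaced_pairs(self):
        w = extract_window(ProteinRecord("p", "AKWAKW"), 3, 2)
        # window AKWAK, k=1 pairs: (A,W),(K,A),(W,K)
        feats = encode_cksaap(w, k=1)
        assert feats["CKSAAP.k1.AW"] == pytest.approx(1 / 3)
        assert feats["CKSAAP.k1.KA"] == pytest.approx(1 / 3)
        assert feats["CKSAAP.k1.WK"] == pytest.approx(1 / 3)


class TestKnnDistance:
    def test_identical_max_scoring_windows_distance_zero(self, blosum):
        from acetylsite.seq_features import knn_distance

        w = window_from("W" * 13, 7)  # BLOSUM62 W-W = max(M) = 11
        assert knn_distance(w, w, blosum) == pytest.approx(0.0)

    def test_all_min_pairs_distance_one(self, blosum):
        from acetylsite.seq_features import knn_distance

        # BLOSUM62 min is -4 (e.g. W vs D)
        w1 = window_from("W" * 13, 7)
        w2 = window_from("D" * 13, 7)
        assert blosum.score("W", "D") == blosum.min
        assert knn_distance(w1, w2, blosum) == pytest.approx(1.0)

    def test_symmetry_and_range(self, blosum):
        from acetylsite.seq_features import knn_distance

        rng = random.Random(5)
        for _ in range(20):
            w1, w2 = random_window(rng), random_window(rng)
            d12 = knn_distance(w1, w2, blosum)
            assert d12 == pytest.approx(knn_distance(w2, w1, blosum))
            assert 0.0 <= d12 <= 1.0

    def test_radius_mismatch_raises(self, blosum):
        from acetylsite.seq_features import knn_distance

        with pytest.raises(ContractError):
            knn_distance(window_from("A" * 13, 7, L=6), window_from("A" * 13, 7, L=5), blosum)


class TestEncodeKnn:
    def make_reference(self, rng, blosum, n=20, L=6):
        frags = []
        for i in range(n):
            w = random_window(rng, L=L, pid=f"ref{i}", pos=None)
            frags.append((w, "positive" if rng.random() < 0.5 else "negative"))
        return KnnReference(fragments=frags, substitution=blosum)

    def test_self_match_with_k1(self, blosum):
        rng = random.Random(6)
        ref = self.make_reference(rng, blosum, n=4)
        # force first fragment positive, query identical to it
        frags = [(ref.fragments[0][0], "positive")] + ref.fragments[1:]
        ref = KnnReference(fragments=frags, substitution=blosum, fractions=(1 / 4,))
        query = frags[0][0]
        scores = encode_knn(query, ref, exclude_self=False)
        assert scores["KNN.f1_4"] == 1.0  # K = 1, nearest is its identical twin

    def test_all_negative_reference_scores_zero(self, blosum):
        rng = random.Random(7)
        frags = [(random_window(rng, pid=f"r{i}"), "negative") for i in range(16)]
        ref = KnnReference(fragments=frags, substitution=blosum)
        assert set(encode_knn(random_window(rng), ref, exclude_self=False).values()) == {0.0}

    def test_matches_brute_force_on_small_references(self, blosum):
        from acetylsite.seq_features import knn_distance

        rng = random.Random(8)
        for trial in range(6):
            n = rng.randint(8, 50)
            frags = [
                (random_window(rng, pid=f"t{trial}r{i}"),
                 "positive" if rng.random() < 0.4 else "negative")
                for i in range(n)
            ]
            ref = KnnReference(fragments=frags, substitution=blosum)
            q = random_window(rng, pid="query")
            got = encode_knn(q, ref, exclude_self=True)
            dists = [knn_distance(q, w, blosum) for w, _ in frags]
            order = sorted(range(n), key=lambda i: (dists[i], i))
            for f in ref.fractions:
                K = max(1, int(math.floor(f * n + 0.5)))
                top = order[:K]
                expected = sum(frags[i][1] == "positive" for i in top) / K
                tag = f"KNN.f1_{int(round(1 / f))}"
                assert got[tag] == pytest.approx(expected)

    def test_exclude_self_changes_leaky_score(self, blosum):
        rng = random.Random(9)
        w = random_window(rng, pid="q", pos=None)
        frags = [(w, "positive")] + [
            (random_window(rng, pid=f"r{i}"), "negative") for i in range(7)
        ]
        ref = KnnReference(fragments=frags, substitution=blosum, fractions=(1 / 8,))
        leaky = encode_knn(w, ref, exclude_self=False)["KNN.f1_8"]
        honest = encode_knn(w, ref, exclude_self=True)["KNN.f1_8"]
        assert leaky == 1.0 and honest == 0.0


class TestACC:
    def test_constant_property_gives_zero(self):
        w = window_from("A" * 13, 7)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in encode_acc(w).values())

    def test_dimensionality(self):
        rng = random.Random(10)
        feats = encode_acc(random_window(rng), max_lag=2)
        assert len(feats) == 2 * 5 * 5

    def test_matches_brute_force(self):
        rng = random.Random(11)
        props = atchley_factors()
        for _ in range(10):
            w = random_window(rng)
            got = encode_acc(w, max_lag=2)
            seq = [r for r, v in zip(w.residues, w.valid_mask) if v]
            nv = len(seq)
            for g in (1, 2):
                for pu in props:
                    for pv in props:
                        xu = [pu[r] for r in seq]
                        xv = [pv[r] for r in seq]
                        mu = sum(xu) / nv
                        mv = sum(xv) / nv
                        expected = sum(
                            (xu[i] - mu) * (xv[i + g] - mv) for i in range(nv - g)
                        ) / (nv - g)
                        kind = "ac" if pu.name == pv.name else "cc"
                        key = f"ACC.{kind}.g{g}.{pu.name}.{pv.name}"
                        assert got[key] == pytest.approx(expected, abs=1e-10)

    def test_too_few_valid_positions_raises(self):
        w = extract_window(ProteinRecord("p", "AK"), 1, 6)
        with pytest.raises(ContractError):
            encode_acc(w, max_lag=2)


class TestPCPseAAC:
    def test_components_sum_to_one(self):
        rng = random.Random(12)
        for _ in range(15):
            feats = encode_pc_pseaac(random_window(rng))
            assert sum(feats.values()) == pytest.approx(1.0)

    def test_lambda_zero_is_plain_composition(self):
        w = window_from("AKAKAKKKKKKAA", 7)
        feats = encode_pc_pseaac(w, lam=0)
        assert feats["PC-PseAAC.comp.A"] == pytest.approx(5 / 13)
        assert feats["PC-PseAAC.comp.K"] == pytest.approx(8 / 13)

    def test_correlation_factors_match_brute_force(self):
        rng = random.Random(13)
        scales = [t.standardized() for t in pseaac_scales()]
        for _ in range(10):
            w = random_window(rng)
            lam, wgt = 2, 0.05
            feats = encode_pc_pseaac(w, lam=lam, weight=wgt)
            seq = [r for r, v in zip(w.residues, w.valid_mask) if v]
            nv = len(seq)
            thetas = []
            for k in range(1, lam + 1):
                tot = 0.0
                for i in range(nv - k):
                    a, b = seq[i], seq[i + k]
                    tot += sum((s[a] - s[b]) ** 2 for s in scales) / 3
                thetas.append(tot / (nv - k))
            denom = 1 + wgt * sum(thetas)
            for k in range(1, lam + 1):
                assert feats[f"PC-PseAAC.theta.{k}"] == pytest.approx(
                    wgt * thetas[k - 1] / denom
                )

    def test_lambda_exceeding_length_raises(self):
        w = extract_window(ProteinRecord("p", "AK"), 1, 6)
        with pytest.raises(ContractError):
            encode_pc_pseaac(w, lam=5)


class TestAAindex:
    def test_homopolymer_average_equals_table_value(self):
        w = window_from("A" * 13, 7)
        feats = encode_aaindex(w)
        for table in default_averaged_tables():
            assert feats[f"AAindex.avg.{table.name}"] == pytest.approx(table["A"])

    def test_default_per_position_count(self):
        w = window_from("A" * 13, 7)
        feats = encode_aaindex(w)
        pos_feats = [k for k in feats if k.startswith("AAindex.pos.")]
        assert len(pos_feats) == 5 * 13
        assert len(feats) == 10 + 65

    def test_masked_average_excludes_invalid(self):
        # window at position 2 of length-13 sequence: 5 invalid positions
        seq = "A" * 13
        w = window_from(seq, 2)
        feats = encode_aaindex(w)
        table = default_averaged_tables()[0]
        assert w.n_valid == 8
        assert feats[f"AAindex.avg.{table.name}"] == pytest.approx(table["A"])

    def test_invalid_positions_zero_in_per_position(self):
        w = window_from("A" * 13, 2)
        feats = encode_aaindex(w)
        factor = atchley_factors()[0].name
        assert feats[f"AAindex.pos.{factor}.j-6"] == 0.0
        assert feats[f"AAindex.pos.{factor}.j0"] == atchley_factors()[0]["A"]


class TestPurity:
    def test_encoders_are_pure(self, blosum):
        rng = random.Random(14)
        w = random_window(rng)
        ref = KnnReference(
            fragments=[(random_window(rng, pid=f"r{i}"), "positive") for i in range(8)],
            substitution=blosum,
        )
        for enc in (
            encode_lc, encode_pwaa, encode_ebgw, encode_cksaap,
            lambda x: encode_knn(x, ref, exclude_self=False),
            encode_acc, encode_pc_pseaac, encode_aaindex,
        ):
            assert enc(w) == enc(w)
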