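"""Model probes: ISM mechanics, insertions, variants, reporters, AUROC."""

import itertools

import numpy as np
import pandas as pd
import pytest

from decaykit import interrogate as ig
from decaykit.encoding import encode_mrna
from decaykit.saluki import SalukiHyperparams, SalukiModel
from decaykit.transcripts import TranscriptModel

from conftest import make_transcript

L_MAX = 256


@pytest.fixture(scope="module")
def predictor():
    """An (untrained) network is a deterministic nonlinear scorer --
    sufficient for the mechanical contracts probed here."""
    h = SalukiHyperparams(l_max=L_MAX, channels=8, n_conv=4, dropout=0.0,
                          heads=("human",))
    model = SalukiModel(h, seed=5)
    return ig.make_predictor(model, "human")


@pytest.fixture
def mid_transcript():
    return make_transcript(
        utr5="ACGU" * 8,
        orf="AUG" + "GACUUU" * 12 + "UAA",
        utr3="CUGA" * 12,
        junctions=(20, 60),
    )


class TestIsm:
    def test_padding_positions_rejected(self, predictor, mid_transcript):
        with pytest.raises(ValueError, match="padding"):
            ig.ism(predictor, mid_transcript, L_MAX,
                   positions=[mid_transcript.length + 3])

    def test_truncated_positions_rejected(self, predictor):
        t = make_transcript(utr5="A" * 200, orf="AUG" + "CCC" * 40 + "UAA",
                            utr3="G" * 100)
        assert t.length > L_MAX
        with pytest.raises(ValueError, match="truncated"):
            ig.ism(predictor, t, L_MAX, positions=[0])

    def test_deltas_cover_three_alternatives(self, predictor, mid_transcript):
        track = ig.ism(predictor, mid_transcript, L_MAX, positions=[5, 40])
        assert track.deltas.shape == (2, 3)
        ref5 = mid_transcript.spliced_seq[5]
        assert ref5 not in track.alts[0]
        assert np.isfinite(track.deltas).all()

    def test_matches_variant_effect_exactly(self, predictor, mid_transcript):
        pos = 40
        ref = mid_transcript.spliced_seq[pos]
        track = ig.ism(predictor, mid_transcript, L_MAX, positions=[pos])
        for j, alt in enumerate(track.alts[0]):
            ve = ig.variant_effect(predictor, mid_transcript, pos, ref, alt,
                                   L_MAX)
            assert ve == pytest.approx(float(track.deltas[0, j]), abs=1e-6)

    def test_self_substitution_is_zero(self, predictor, mid_transcript):
        pos = 12
        ref = mid_transcript.spliced_seq[pos]
        assert ig.variant_effect(
            predictor, mid_transcript, pos, ref, ref, L_MAX
        ) == 0.0


class TestIsmMetagene:
    def _tracks(self, transcripts, fill):
        out = {}
        for g, t in transcripts.items():
            n = t.length
            out[g] = ig.IsmTrack(
                gene_id=g,
                positions=np.arange(n),
                alts=np.full((n, 3), "A"),
                deltas=np.full((n, 3), fill),
                ref_prediction=0.0,
            )
        return out

    def test_all_zero_tracks_give_zero_metagene(self):
        ts = {f"g{i}": make_transcript(gene=f"g{i}") for i in range(8)}
        tracks = self._tracks(ts, 0.0)
        pred = pd.Series(np.linspace(0, 1, 8), index=list(ts))
        mg = ig.ism_metagene(tracks, ts, pred, n_bins=5)
        assert (mg == 0).all()

    def test_each_transcript_in_exactly_one_quartile(self):
        ts = {f"g{i}": make_transcript(gene=f"g{i}") for i in range(8)}
        pred = pd.Series(np.arange(8, dtype=float), index=list(ts))
        q = pd.qcut(pred, 4, labels=[1, 2, 3, 4])
        assert (q.value_counts() == 2).all()

    def test_permutation_invariance_to_input_order(self):
        ts = {f"g{i}": make_transcript(gene=f"g{i}") for i in range(6)}
        rng = np.random.default_rng(0)
        tracks = {}
        for g, t in ts.items():
            n = t.length
            tracks[g] = ig.IsmTrack(g, np.arange(n), np.full((n, 3), "A"),
                                    rng.normal(size=(n, 3)), 0.0)
        pred = pd.Series(rng.normal(size=6), index=list(ts))
        mg1 = ig.ism_metagene(tracks, ts, pred, n_bins=4)
        order = list(ts)[::-1]
        mg2 = ig.ism_metagene({g: tracks[g] for g in order},
                              {g: ts[g] for g in order}, pred, n_bins=4)
        pd.testing.assert_series_equal(mg1.sort_index(), mg2.sort_index())


class TestInsertionScan:
    def test_short_utr5_excludes_transcript(self, predictor):
        short = make_transcript(utr5="A" * 99, orf="AUG" + "C" * 57 + "UAA",
                                utr3="G" * 80)
        with pytest.raises(ValueError, match="validity"):
            ig.insert_motif_scan(
                predictor, {"g": short}, "UAUUUAU", L_MAX,
                min_utr5=100, min_orf=50, min_utr3=50,
            )

    def test_inserting_local_reference_gives_zero_delta(self, predictor):
        t = make_transcript(utr5="A" * 30, orf="AUG" + "GAC" * 30 + "UAA",
                            utr3="U" * 60)
        prof = ig.insert_motif_scan(
            predictor, {"g": t}, "UUUU", L_MAX, bins=5,
            min_utr5=10, min_orf=30, min_utr3=20, regions=("utr3",),
        )
        assert np.allclose(prof.table["mean_delta"], 0.0, atol=1e-7)

    def test_rejects_kmer_outside_alphabet(self, predictor, mid_transcript):
        with pytest.raises(ValueError, match="ACGU"):
            ig.insert_motif_scan(predictor, {"g": mid_transcript}, "ACGT",
                                 L_MAX)

    def test_codon_scan_zero_delta_for_resident_codon(self, predictor):
        t = make_transcript(utr5="A" * 20, orf="AUG" + "GAC" * 40 + "UAA",
                            utr3="C" * 40)
        table, per_codon = ig.insert_codon_scan(
            predictor, {"g": t}, L_MAX, codons=("GAC",), bins=4,
            min_utr5=10, min_orf=60, min_utr3=20,
        )
        # bin 0 anchors on the start codon itself, so only the bins whose
        # anchor falls inside the GAC repeat must be exactly zero
        assert np.allclose(table.loc["GAC", 1:], 0.0, atol=1e-7)
        assert abs(table.loc["GAC", 0]) > 0  # replacing AUG is a real change

    def test_profiles_permutation_invariant(self, predictor):
        ts = {
            f"g{i}": make_transcript(
                gene=f"g{i}",
                utr5="ACGU" * (5 + i),
                orf="AUG" + "GAC" * (25 + i) + "UAA",
                utr3="CAGU" * (10 + i),
            )
            for i in range(4)
        }
        kw = dict(bins=4, min_utr5=10, min_orf=30, min_utr3=20)
        a = ig.insert_motif_scan(predictor, ts, "UAUU", L_MAX, **kw)
        rev = {g: ts[g] for g in list(ts)[::-1]}
        b = ig.insert_motif_scan(predictor, rev, "UAUU", L_MAX, **kw)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestSpliceMarkEffect:
    def test_no_orf_junctions_gives_empty_series(self, predictor):
        t = make_transcript(junctions=(2,))  # junction in the 5'UTR
        out = ig.splice_mark_effect(predictor, t, L_MAX)
        assert out.empty

    def test_one_delta_per_orf_junction(self, predictor, mid_transcript):
        out = ig.splice_mark_effect(predictor, mid_transcript, L_MAX)
        lo, hi = mid_transcript.region_bounds("orf")
        expected = [j for j in mid_transcript.exon_junctions if lo < j < hi]
        assert list(out.index) == expected


class TestVariantAndReporter:
    def test_reference_mismatch_names_observed_base(self, predictor,
                                                    mid_transcript):
        pos = 7
        actual = mid_transcript.spliced_seq[pos]
        wrong = "A" if actual != "A" else "C"
        with pytest.raises(ValueError, match=actual):
            ig.variant_effect(predictor, mid_transcript, pos, wrong, "G",
                              L_MAX)

    def test_smoothing_constant_track_unchanged(self):
        x = np.full(40, 1.7)
        assert np.allclose(ig.smooth_track(x, window=8), 1.7)

    def test_smoothing_is_local_mean(self):
        x = np.zeros(20)
        x[10] = 8.0
        sm = ig.smooth_track(x, window=8)
        assert sm[10] == pytest.approx(1.0)  # 8 / window
        assert sm[0] == 0.0

    def test_empty_fragment_equals_scaffold_baseline(self, predictor,
                                                     mid_transcript):
        site = mid_transcript.utr5_len + mid_transcript.orf_len + 4
        rc = ig.ReporterConstruct(mid_transcript, insert_site=site)
        base = predictor(encode_mrna(mid_transcript, L_MAX).tensor[None])[0]
        assert ig.reporter_effect(predictor, rc, "", L_MAX) == pytest.approx(
            float(base)
        )

    def test_fragment_insertion_preserves_flanks_and_shifts_junctions(self):
        t = make_transcript(junctions=(5, 40))
        site = t.utr5_len + t.orf_len + 2
        rc = ig.ReporterConstruct(t, insert_site=site)
        chim = ig.build_chimera(rc, "UAUUUAU")
        assert chim.length == t.length + 7
        assert chim.spliced_seq[:site] == t.spliced_seq[:site]
        assert chim.spliced_seq[site:site + 7] == "UAUUUAU"
        assert chim.exon_junctions == (5, 47)

    def test_single_base_fragment_difference_equals_variant_effect(
        self, predictor, mid_transcript
    ):
        site = mid_transcript.utr5_len + mid_transcript.orf_len + 4
        rc = ig.ReporterConstruct(mid_transcript, insert_site=site)
        fa, fb = "ACGUACGU", "ACGAACGU"
        delta_rep = (
            ig.reporter_effect(predictor, rc, fb, L_MAX)
            - ig.reporter_effect(predictor, rc, fa, L_MAX)
        )
        chim = ig.build_chimera(rc, fa)
        ve = ig.variant_effect(predictor, chim, site + 3, "U", "A", L_MAX)
        assert delta_rep == pytest.approx(ve, abs=1e-6)

    def test_insert_site_outside_utr3_rejected(self, mid_transcript):
        with pytest.raises(ValueError, match="3'UTR"):
            ig.ReporterConstruct(mid_transcript, insert_site=2)


class TestMatchedVariantBenchmark:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["pip", "region", "expression", "gene", "abs_delta"]
        )

    def test_perfect_separation_gives_auroc_one(self):
        df = self._table(
            [(0.95, "utr3", 1.0, f"p{i}", 0.9 + i / 100) for i in range(3)]
            + [(0.001, "utr3", 1.0, f"n{i}", 0.1 + i / 100) for i in range(3)]
        )
        out = ig.matched_variant_benchmark(df)
        assert out["auroc"] == 1.0

    def test_identical_scores_give_half(self):
        df = self._table(
            [(0.95, "orf", 1.0, f"p{i}", 0.5) for i in range(4)]
            + [(0.001, "orf", 1.0, f"n{i}", 0.5) for i in range(4)]
        )
        assert ig.matched_variant_benchmark(df)["auroc"] == 0.5

    def test_three_by_three_example_matches_pair_enumeration(self):
        pos_scores = [0.9, 0.8, 0.7]
        neg_scores = [0.6, 0.85, 0.1]
        # enumeration oracle over all 9 positive-negative pairs: the
        # negative scored 0.85 outranks two of the three positives
        wins = sum(
            1.0 if p > n else 0.5 if p == n else 0.0
            for p, n in itertools.product(pos_scores, neg_scores)
        )
        assert wins / 9 == pytest.approx(7 / 9)
        df = self._table(
            [(0.95, "utr3", float(i), f"p{i}", s)
             for i, s in enumerate(pos_scores)]
            + [(0.001, "utr3", float(i), f"n{i}", s)
               for i, s in enumerate(neg_scores)]
        )
        out = ig.matched_variant_benchmark(df)
        assert out["auroc"] == pytest.approx(wins / 9)

    def test_negative_matching_rules(self):
        df = self._table([
            (0.95, "utr3", 5.0, "gpos", 0.9),     # positive
            (0.001, "orf", 5.0, "gA", 0.2),       # wrong region
            (0.001, "utr3", 5.1, "gpos", 0.2),    # same gene
            (0.001, "utr3", 4.0, "gB", 0.2),      # |diff|=1.0
            (0.001, "utr3", 5.3, "gC", 0.2),      # |diff|=0.3 -> chosen
        ])
        out = ig.matched_variant_benchmark(df)
        assert out["pairs"].loc[0, "negative"] == 4

    def test_without_replacement_and_error_when_exhausted(self):
        df = self._table([
            (0.95, "utr3", 1.0, "p1", 0.9),
            (0.95, "utr3", 1.1, "p2", 0.8),
            (0.001, "utr3", 1.0, "n1", 0.2),
        ])
        with pytest.raises(ValueError, match="insufficient"):
            ig.matched_variant_benchmark(df)


class TestLengthPreservation:
    def test_all_substitution_probes_preserve_length(self, predictor,
                                                     mid_transcript):
        t = mid_transcript
        lengths = []
        orig_encoded = encode_mrna(t, L_MAX)

        def spy(X):
            lengths.append(X.shape[1])
            return np.zeros(X.shape[0], dtype=np.float32)

        ig.ism(spy, t, L_MAX, positions=[3, 9])
        ig.insert_motif_scan(spy, {"g": t}, "UAUU", L_MAX, bins=3,
                             min_utr5=5, min_orf=20, min_utr3=10)
        assert set(lengths) == {L_MAX}
        assert orig_encoded.true_length == t.length
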