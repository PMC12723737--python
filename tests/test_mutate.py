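"""Saturation-mutagenesis enumeration, mutation application and screening."""

import numpy as np
import pytest

from phopt.embed import FixtureEmbedder
from phopt.exceptions import ParseError, ValidationError
from phopt.io import STANDARD_AA
from phopt.mutate import (MutationSpec, ScreenConfig, apply_mutation,
                          enumerate_mutants, parse_mutation, read_candidates,
                          screen, window_positions, write_candidates)
from phopt.network import ModelConfig, init_state
from phopt.synth import SyntheticSpec, generate_dataset
from phopt.train import TrainingConfig, train


def _random_seq(rng, n):
    return "".join(rng.choice(list(STANDARD_AA), size=n))


class TestEnumeration:
    def test_reference_window_count(self, rng):
        """3 windows of 21 sites -> 63 positions x 19 substitutions = 1197."""
        seq = _random_seq(rng, 170)
        specs = enumerate_mutants(seq, ScreenConfig(centers=(46, 92, 152),
                                                    radius=10))
        assert len(specs) == 1197

    def test_overlapping_windows_deduplicated(self, rng):
        seq = _random_seq(rng, 20)
        specs = enumerate_mutants(seq, ScreenConfig(centers=(5, 7), radius=2))
        # union {3..9} via brute-force set construction
        expected_positions = set(range(3, 8)) | set(range(5, 10))
        assert {s.position for s in specs} == expected_positions
        assert len(specs) == 7 * 19 == 133

    def test_radius_zero_gives_19_non_wildtype(self, rng):
        seq = _random_seq(rng, 30)
        specs = enumerate_mutants(seq, ScreenConfig(centers=(10,), radius=0))
        assert len(specs) == 19
        assert all(s.mut_aa != seq[9] for s in specs)

    def test_windows_clipped_at_ends(self, rng):
        seq = _random_seq(rng, 12)
        specs = enumerate_mutants(seq, ScreenConfig(centers=(2,), radius=5))
        assert {s.position for s in specs} == set(range(1, 8))

    def test_count_matches_brute_force_for_random_configs(self, rng):
        seq = _random_seq(rng, 60)
        for _ in range(10):
            centers = tuple(rng.integers(1, 61, size=rng.integers(1, 4)))
            radius = int(rng.integers(0, 12))
            cfg = ScreenConfig(centers=centers, radius=radius)
            brute = set()
            for c in centers:
                for p in range(c - radius, c + radius + 1):
                    if 1 <= p <= 60:
                        brute.add(p)
            specs = enumerate_mutants(seq, cfg)
            assert len(specs) == 19 * len(brute)
            assert len({s.name for s in specs}) == len(specs)  # unique

    def test_canonical_order(self, rng):
        seq = _random_seq(rng, 30)
        specs = enumerate_mutants(seq, ScreenConfig(centers=(10,), radius=2))
        keys = [(s.position, s.mut_aa) for s in specs]
        assert keys == sorted(keys)

    def test_center_out_of_range(self):
        with pytest.raises(ValidationError):
            window_positions("MKVAC", ScreenConfig(centers=(9,)))

    def test_nonstandard_residue_in_window_named(self):
        with pytest.raises(ValidationError, match="position 3"):
            enumerate_mutants("MKXAC", ScreenConfig(centers=(3,), radius=1))


class TestApplyMutation:
    def test_substitution(self):
        assert apply_mutation("MHA", MutationSpec(2, "H", "C")) == "MCA"

    def test_involution(self):
        seq = "MKVACDE"
        spec = MutationSpec(4, "A", "W")
        mutated = apply_mutation(seq, spec)
        back = apply_mutation(mutated, MutationSpec(4, "W", "A"))
        assert back == seq

    def test_hamming_distance_one(self, rng):
        seq = _random_seq(rng, 40)
        pos = int(rng.integers(1, 41))
        aa = next(a for a in STANDARD_AA if a != seq[pos - 1])
        mutated = apply_mutation(seq, MutationSpec(pos, seq[pos - 1], aa))
        assert sum(a != b for a, b in zip(seq, mutated)) == 1

    def test_wildtype_mismatch_quotes_letters(self):
        with pytest.raises(ValidationError, match="expected.*'H'.*found.*'M'"):
            apply_mutation("MKV", MutationSpec(1, "H", "C"))


class TestMutationNames:
    def test_bijective_parse_format(self):
        spec = parse_mutation("H44C")
        assert spec == MutationSpec(44, "H", "C")
        assert spec.name == "H44C"

    @pytest.mark.parametrize("bad", ["44C", "H44", "HXC", "h44c", "H44CC"])
    def test_malformed_names(self, bad):
        with pytest.raises(ParseError):
            parse_mutation(bad)

    def test_wildtype_equal_mutant_rejected(self):
        with pytest.raises(ValidationError):
            MutationSpec(4, "A", "A")


@pytest.fixture(scope="module")
def setup():
    rng = np.random.default_rng(6)
    seq = _random_seq(rng, 60)
    emb = FixtureEmbedder(dim=8, seed=6)
    state = init_state(ModelConfig(dim=8, n_head=2, n_rd=2, seed=6))
    return seq, emb, state


class TestScreen:
    def _constant_state(self, value):
        state = init_state(ModelConfig(dim=8, n_head=2, n_rd=2, seed=6))
        state.params["head_w"][:] = 0
        state.params["head_b"] = np.asarray(value / 14.0)
        return state

    def test_constant_above_threshold_selects_none(self, setup):
        seq, emb, _ = setup
        table = screen(seq, ScreenConfig(centers=(30,), radius=3),
                       self._constant_state(7.5), emb)
        assert len(table) == 7 * 19
        assert not table.frame["selected"].any()

    def test_constant_below_threshold_selects_all(self, setup):
        seq, emb, _ = setup
        table = screen(seq, ScreenConfig(centers=(30,), radius=3),
                       self._constant_state(6.5), emb)
        assert table.frame["selected"].all()

    def test_threshold_monotonicity(self, setup):
        seq, emb, state = setup
        low = screen(seq, ScreenConfig(centers=(30,), radius=5,
                                       ph_threshold=6.5), state, emb)
        high = screen(seq, ScreenConfig(centers=(30,), radius=5,
                                        ph_threshold=8.5), state, emb)
        low_sel = set(low.frame.loc[low.frame["selected"], "mutation"])
        high_sel = set(high.frame.loc[high.frame["selected"], "mutation"])
        assert low_sel <= high_sel

    def test_determinism(self, setup):
        seq, emb, state = setup
        cfg = ScreenConfig(centers=(30,), radius=4)
        a = screen(seq, cfg, state, emb)
        b = screen(seq, cfg, state, emb)
        assert a.frame.equals(b.frame)

    def test_acidifying_substitutions_rank_best_on_trained_model(self):
        """A model trained on composition-driven labels should predict lower
        pH_opt for substitutions to acidic residues than to basic ones."""
        recs = generate_dataset(SyntheticSpec(n=300, seed=11,
                                              length_range=(25, 50)))
        emb = FixtureEmbedder(dim=16, seed=11)
        state, _ = train(ModelConfig(dim=16, seed=11),
                         TrainingConfig(n_epochs=10, seed=11), recs, emb)
        seq = "GAVLIPFMWGAVLIPFMWGAVLIPFMWGAV"  # neutral background
        table = screen(seq, ScreenConfig(centers=(15,), radius=5),
                       state, emb).frame
        to_acidic = table[table["mut"].isin(list("DE"))]["predicted_ph_opt"]
        to_basic = table[table["mut"].isin(list("KR"))]["predicted_ph_opt"]
        assert to_acidic.mean() < to_basic.mean()

    def test_activity_scorer_topk_and_errors(self, setup):
        seq, emb, _ = setup
        state = self._constant_state(6.0)

        def scorer(s):
            if s[29] == "W":  # fail on one specific mutant
                raise RuntimeError("scorer crash")
            return float(sum(aa in "DE" for aa in s))

        cfg = ScreenConfig(centers=(30,), radius=0, top_k=3)
        table = screen(seq, cfg, state, emb, activity_scorer=scorer)
        assert table.errors == 1
        assert table.frame["selected"].sum() == 3
        # all predictions tie -> selection ranked by descending activity
        sel = table.frame[table.frame["selected"]]
        assert set(sel["mut"]) >= {"D", "E"}

    def test_activity_table_lookup(self, setup):
        seq, emb, _ = setup
        state = self._constant_state(6.0)
        specs = enumerate_mutants(seq, ScreenConfig(centers=(30,), radius=0))
        scores = {s.name: float(i) for i, s in enumerate(specs)}
        cfg = ScreenConfig(centers=(30,), radius=0, top_k=2)
        table = screen(seq, cfg, state, emb, activity_scorer=scores)
        sel = table.frame[table.frame["selected"]]
        # all predictions tie, so the two highest-activity mutants win
        assert sorted(sel["activity_score"]) == sorted(scores.values())[-2:]


class TestCandidateIO:
    def test_roundtrip(self, tmp_path, rng):
        seq = _random_seq(rng, 170)
        emb = FixtureEmbedder(dim=8, seed=1)
        state = init_state(ModelConfig(dim=8, n_head=2, n_rd=2, seed=1))
        table = screen(seq, ScreenConfig(centers=(46, 92, 152), radius=10),
                       state, emb)
        assert len(table) == 1197
        path = tmp_path / "candidates.tsv"
        write_candidates(table, path)
        back = read_candidates(path)
        assert len(back) == 1197
        merged = back.frame.sort_values(["position", "mut"]).reset_index(
            drop=True)
        orig = table.frame.sort_values(["position", "mut"]).reset_index(
            drop=True)
        assert merged["mutation"].tolist() == orig["mutation"].tolist()
        assert np.allclose(merged["predicted_ph_opt"],
                           orig["predicted_ph_opt"])

    def test_rows_sorted_canonically_on_write(self, tmp_path):
        import pandas as pd

        from phopt.mutate import CandidateTable

        frame = pd.DataFrame({
            "mutation": ["H4C", "A2D"], "position": [4, 2],
            "wt": ["H", "A"], "mut": ["C", "D"],
            "predicted_ph_opt": [6.0, 7.0],
            "activity_score": [np.nan, np.nan],
            "selected": [True, False], "error": [False, False]})
        path = tmp_path / "c.tsv"
        write_candidates(CandidateTable(frame), path)
        back = read_candidates(path)
        assert back.frame["mutation"].tolist() == ["A2D", "H4C"]

    def test_malformed_name_on_read(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("mutation\tposition\twt\tmut\tpredicted_ph_opt\t"
                        "activity_score\tselected\terror\n"
                        "notaname\t1\tA\tB\t6.0\t\tTrue\tFalse\n")
        with pytest.raises(ParseError):
            read_candidates(path)
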