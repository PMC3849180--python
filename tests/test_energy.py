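"""Duplex minimum-free-energy dynamic program."""

import math

import numpy as np
import pytest

from mirconsensus.energy import (
    _reverse_doublet,
    duplex_mfe,
    load_parameters,
    score_sites,
    structure_energy,
)
from mirconsensus.sites import TranscriptRecord, reverse_complement_rna, scan_seed_sites
from mirconsensus.synthetic import MIR100
from oracles import enumerate_duplex_mfe

_RNA = list("ACGU")


def _random_pairs(n_cases, max_len, seed):
    rng = np.random.default_rng(seed)
    for _ in range(n_cases):
        m = int(rng.integers(2, max_len + 1))
        n = int(rng.integers(2, max_len + 1))
        yield (
            "".join(rng.choice(_RNA, size=m)),
            "".join(rng.choice(_RNA, size=n)),
        )


class TestParameters:
    def test_reversal_symmetry_as_shipped(self, params):
        for key, e in params.stack_energy.items():
            assert params.stack_energy[_reverse_doublet(key)] == e

    def test_watson_crick_stacks_are_stabilizing(self, params):
        wc = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
        for key, e in params.stack_energy.items():
            if (key[0], key[3]) in wc and (key[1], key[4]) in wc:
                assert e < 0

    def test_loop_penalties_nonnegative_and_nondecreasing(self, params):
        last_bulge = last_internal = 0.0
        for size in range(1, 30):
            bulge = params.loop_penalty(size, 0)
            assert bulge >= last_bulge >= 0
            last_bulge = bulge
            internal = params.loop_penalty(size, 1)
            assert internal >= last_internal >= 0
            last_internal = internal


class TestDuplexMfe:
    def test_perfect_four_pair_duplex_closed_form(self, params):
        result = duplex_mfe("GGGG", "CCCC", params)
        expected = params.duplex_init + 3 * params.stack_energy["GG/CC"]
        assert result.mfe == pytest.approx(expected)
        assert result.pairing == ((1, 4), (2, 3), (3, 2), (4, 1))

    def test_no_complementarity_means_no_stable_duplex(self, params):
        result = duplex_mfe("AAAA", "AAAA", params)
        assert result.mfe is None
        assert result.pairing == ()

    def test_single_possible_pair_is_not_a_duplex(self, params):
        # one isolated pair lacks the required two consecutive pairs
        assert duplex_mfe("AAC", "GAA", params).mfe is None

    def test_matches_exhaustive_enumeration(self, params):
        checked = 0
        for x, y in _random_pairs(150, 8, seed=23):
            expected = enumerate_duplex_mfe(x, y, params)
            got = duplex_mfe(x, y, params).mfe
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-9)
                checked += 1
        assert checked > 50  # most random pairs do form duplexes

    def test_self_consistency_energy_recomputed_from_pairing(self, params):
        for x, y in _random_pairs(40, 10, seed=29):
            result = duplex_mfe(x, y, params)
            if result.mfe is None:
                continue
            recomputed = structure_energy(result.pairing, x, y, params)
            assert recomputed == pytest.approx(result.mfe, abs=1e-9)

    def test_stackable_end_extension_never_raises_mfe(self, params):
        rng = np.random.default_rng(31)
        complement = dict(zip("ACGU", "UGCA"))
        for _ in range(30):
            m = int(rng.integers(3, 8))
            x = "".join(rng.choice(_RNA, size=m))
            y = reverse_complement_rna(x)
            base = duplex_mfe(x, y, params).mfe
            ext = rng.choice(_RNA)
            extended = duplex_mfe(x + ext, complement[ext] + y, params).mfe
            assert base is not None
            assert extended <= base + 1e-9

    def test_window_shorter_than_2_rejected(self, params):
        with pytest.raises(ValueError):
            duplex_mfe("ACGU", "C", params)

    def test_alphabet_violation_rejected(self, params):
        with pytest.raises(ValueError):
            duplex_mfe("ACGX", "ACGU", params)

    def test_deterministic_tie_break(self, params):
        a = duplex_mfe("ACGUACGU", "ACGUACGU", params)
        b = duplex_mfe("ACGUACGU", "ACGUACGU", params)
        assert a.pairing == b.pairing and a.mfe == b.mfe

    def test_render_mentions_energy(self, params):
        text = duplex_mfe("GGGG", "CCCC", params).render()
        assert "kcal/mol" in text and "|" in text


class TestScoreSites:
    def test_perfect_complement_window_hits_closed_form(self, params):
        rc = reverse_complement_rna(MIR100.sequence).replace("U", "T")
        tx = TranscriptRecord(id="T", sequence=rc)
        sites = scan_seed_sites(tx, MIR100)
        assert len(sites) == 1
        score_sites(sites, tx, MIR100, params)
        closed_form = params.duplex_init + sum(
            params.stack_energy[
                MIR100.sequence[i : i + 2] + "/" + reverse_complement_rna(MIR100.sequence)[::-1][i : i + 2]
            ]
            for i in range(len(MIR100.sequence) - 1)
        )
        assert sites[0].mfe == pytest.approx(closed_form)

    def test_perfect_site_beats_seed_only_site(self, params):
        rc_full = reverse_complement_rna(MIR100.sequence).replace("U", "T")
        seed_only = ("A" * 20 + reverse_complement_rna(MIR100.seed) + "A" * 20).replace("U", "T")
        tx = TranscriptRecord(id="T", sequence=rc_full + "A" * 40 + seed_only)
        sites = scan_seed_sites(tx, MIR100)
        assert len(sites) == 2
        score_sites(sites, tx, MIR100, params)
        perfect, seedish = sites
        assert perfect.mfe < seedish.mfe

    def test_batch_equals_direct_calls(self, default_dataset, params):
        tx = default_dataset.transcripts[0]
        sites = scan_seed_sites(tx, MIR100)
        score_sites(sites, tx, MIR100, params)
        for site in sites:
            window = tx.rna[site.window_start - 1 : site.window_end]
            assert site.mfe == pytest.approx(duplex_mfe(MIR100, window, params).mfe)


def test_parameter_file_roundtrip(tmp_path, params):
    # a user-supplied parameter file goes through the same loader
    copy = tmp_path / "params.tsv"
    lines = ["record\tkey\tvalue"]
    seen = set()
    for key, e in params.stack_energy.items():
        canon = min(key, _reverse_doublet(key))
        if canon not in seen:
            seen.add(canon)
            lines.append(f"stack\t{canon}\t{e}")
    for name in ("duplex_init", "bulge_base", "internal_base", "loop_log_coeff", "max_loop"):
        lines.append(f"param\t{name}\t{getattr(params, name)}")
    copy.write_text("\n".join(lines) + "\n")
    reloaded = load_parameters(copy)
    assert reloaded.stack_energy == params.stack_energy
    assert reloaded.duplex_init == params.duplex_init
    assert math.isclose(reloaded.loop_penalty(3, 2), params.loop_penalty(3, 2))
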