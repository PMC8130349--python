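"""Damage profiler: terminal mis-incorporation tallies, score, model fit.

The profile implementation is cross-checked against a brute-force tally
written here directly on the SAM text, independent of the package code path.
"""

import math

import numpy as np
import pysam
import pytest

import relicdna as r
from relicdna.damage import UndefinedDamageError, damage_score, fit_damage_model


# ---------------------------------------------------------------------------
# hand-constructed fixtures
# ---------------------------------------------------------------------------

def _write_sam(path, reference, rows):
    """rows: (name, flag, pos0, seq). Pure-M alignments."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:ref\tLN:{len(reference)}\n")
        for name, flag, pos0, seq in rows:
            fh.write(f"{name}\t{flag}\tref\t{pos0 + 1}\t60\t{len(seq)}M\t"
                     f"*\t0\t0\t{seq}\t{'I' * len(seq)}\n")


COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _brute_force_profile(sam_path, reference, max_pos=25):
    """Independent per-column tally, straight off the SAM text."""
    ct = np.zeros(max_pos, int)
    opp5 = np.zeros(max_pos, int)
    ga = np.zeros(max_pos, int)
    opp3 = np.zeros(max_pos, int)
    for line in open(sam_path):
        if line.startswith("@"):
            continue
        f = line.rstrip("\n").split("\t")
        flag, pos0, seq = int(f[1]), int(f[3]) - 1, f[9]
        if flag & 4:
            continue
        rev = bool(flag & 16)
        L = len(seq)
        for i, qb in enumerate(seq):
            rb = reference[pos0 + i]
            if rev:
                off5 = L - 1 - i
                rb, qb = COMP[rb], COMP[qb]
            else:
                off5 = i
            off3 = L - 1 - off5
            if off5 < max_pos and rb == "C":
                opp5[off5] += 1
                ct[off5] += qb == "T"
            if off3 < max_pos and rb == "G":
                opp3[off3] += 1
                ga[off3] += qb == "A"
    return ct, opp5, ga, opp3


class TestSubstitutionProfile:
    def test_zero_mismatch_reads_give_zero_frequencies(self, tmp_path):
        ref = "ACGT" * 50
        rows = [(f"r{i}", 0, i, ref[i:i + 60]) for i in range(0, 100, 10)]
        sam = tmp_path / "clean.sam"
        _write_sam(sam, ref, rows)
        prof = r.substitution_profile(sam, {"ref": ref})
        defined = prof.opportunities5 > 0
        assert defined.any()
        assert np.all(prof.ct5[defined] == 0.0)

    def test_hand_counted_ct_fraction(self, tmp_path):
        """Reference C at read 5' offset 1; 3 of 10 reads carry T there."""
        ref = "C" + "A" * 59
        rows = [(f"r{i}", 0, 0, ("T" if i < 3 else "C") + "A" * 39)
                for i in range(10)]
        sam = tmp_path / "toy.sam"
        _write_sam(sam, ref, rows)
        prof = r.substitution_profile(sam, {"ref": ref})
        assert prof.opportunities5[0] == 10
        assert prof.ct_counts[0] == 3
        assert prof.ct5[0] == pytest.approx(0.3)

    def test_reverse_strand_flipped_into_read_orientation(self, tmp_path):
        """A genome-space G->A mismatch at the right end of a flag-16 read
        is a 5' C->T in read orientation."""
        ref = "A" * 39 + "G" + "A" * 20
        rows = [("fwd", 0, 0, "A" * 40),
                ("rev", 16, 0, "A" * 39 + "A")]  # read shows A over ref G
        sam = tmp_path / "rev.sam"
        _write_sam(sam, ref, rows)
        prof = r.substitution_profile(sam, {"ref": ref})
        # for the reverse read, ref G at its right end is read-orientation C
        # at 5' offset 0, and the A base is read-orientation T
        assert prof.opportunities5[0] == 1
        assert prof.ct_counts[0] == 1

    def test_matches_brute_force_on_small_simulated_sam(self, tmp_path):
        """Exact oracle equivalence on <= 50 simulated reads."""
        spec = r.PopulationSpec("g", 5000, 0.5, vitality="dead_intact",
                                damage=r.fossil_damage())
        genomes = r.generate_reference_genomes([spec], seed=13)
        frags = r.simulate_taphonomy(genomes["g"], spec, 1e5, seed=13,
                                     n_fragments=40)
        lib = r.sequence_library(
            frags, genomes,
            r.LibrarySpec("iDNA", False, read_length=60, target_depth=0.55,
                          block_prob=0.0, seq_error_rate=0.01, seed=13))
        assert 0 < len(lib.reads) <= 50
        sam = tmp_path / "small.sam"
        lib.write_sam(sam)
        prof = r.substitution_profile(sam, genomes)
        ct, opp5, ga, opp3 = _brute_force_profile(sam, genomes["g"])
        assert np.array_equal(prof.ct_counts, ct)
        assert np.array_equal(prof.opportunities5, opp5)
        assert np.array_equal(prof.ga_counts, ga)
        assert np.array_equal(prof.opportunities3, opp3)

    def test_general_cigar_path_agrees_with_fast_path(self, tmp_path):
        """An insertion-bearing alignment is tallied per aligned column."""
        ref = "CCCCAAAACCCC"
        header = {"HD": {"VN": "1.6"},
                  "SQ": [{"SN": "ref", "LN": len(ref)}]}
        sam = tmp_path / "indel.sam"
        with pysam.AlignmentFile(sam, "w", header=header) as out:
            a = pysam.AlignedSegment(out.header)
            a.query_name = "ins"
            a.flag = 0
            a.reference_id = 0
            a.reference_start = 0
            a.mapping_quality = 60
            # 4M2I4M: TTTT + GG (inserted) + AAAA over ref CCCCAAAA
            a.cigartuples = [(0, 4), (1, 2), (0, 4)]
            a.query_sequence = "TTTTGGAAAA"
            a.query_qualities = pysam.qualitystring_to_array("I" * 10)
            out.write(a)
        prof = r.substitution_profile(sam, {"ref": ref}, max_pos=10)
        # offsets 0-3 are ref C read T; inserted bases occupy offsets 4-5
        # but align to no reference column and must be skipped
        assert list(prof.ct_counts[:4]) == [1, 1, 1, 1]
        assert prof.opportunities5[4] == 0 and prof.opportunities5[5] == 0

    def test_unknown_reference_is_an_error(self, tmp_path):
        ref = "ACGT" * 10
        sam = tmp_path / "bad.sam"
        _write_sam(sam, ref, [("r0", 0, 0, ref[:20])])
        with pytest.raises(KeyError):
            r.substitution_profile(sam, {"other": ref})

    def test_empty_alignments_give_all_undefined_profile(self):
        prof = r.substitution_profile([], {"ref": "ACGT" * 10})
        assert np.isnan(prof.ct5).all()


class TestEndSymmetry:
    def test_three_prime_ga_mirrors_five_prime_ct(self):
        """Reads spanning whole fragments see both damaged termini: ga3 at
        the 3' end tracks ct5 at the 5' end; reads too short to reach the
        fragment 3' end see only the sequencing-error floor there."""
        dmg = r.DamageParams(delta_ss=0.3, delta_ds=0.0, q=0.5,
                             frag_mu=math.log(80.0), frag_sigma=0.1)
        spec = r.PopulationSpec("g", 50_000, 0.5, vitality="dead_intact",
                                damage=dmg)
        genomes = r.generate_reference_genomes([spec], seed=14)
        frags = r.simulate_taphonomy(genomes["g"], spec, 1e5, seed=14,
                                     n_fragments=20_000)
        spanning = r.sequence_library(
            frags, genomes,
            r.LibrarySpec("iDNA", False, read_length=150, target_depth=30.0,
                          block_prob=0.0, seq_error_rate=0.0, seed=14))
        prof = r.substitution_profile(
            (self._records(spanning)), genomes)
        assert prof.ct5[0] == pytest.approx(0.3, abs=0.02)
        assert prof.ga3[0] == pytest.approx(0.3, abs=0.02)
        truncated = r.sequence_library(
            frags, genomes,
            r.LibrarySpec("iDNA", False, read_length=40, target_depth=10.0,
                          block_prob=0.0, seq_error_rate=0.0, seed=14))
        prof_t = r.substitution_profile(self._records(truncated), genomes)
        assert prof_t.ct5[0] == pytest.approx(0.3, abs=0.02)
        assert prof_t.ga3[0] < 0.02  # 3' fragment end never sequenced

    @staticmethod
    def _records(lib):
        import io as _io_mod
        import tempfile
        import os
        fd, path = tempfile.mkstemp(suffix=".sam")
        os.close(fd)
        lib.write_sam(path)
        return path


class TestDamageScore:
    def test_score_is_terminal_frequency(self, tmp_path):
        ref = "C" + "A" * 59
        sam = tmp_path / "s.sam"
        _write_sam(sam, ref, [(f"r{i}", 0, 0, ("T" if i == 0 else "C") + "A" * 30)
                              for i in range(20)])
        prof = r.substitution_profile(sam, {"ref": ref})
        assert damage_score(prof) == pytest.approx(0.05)

    def test_undefined_without_terminal_opportunities(self):
        prof = r.substitution_profile([], {"ref": "ACGT" * 10})
        with pytest.raises(UndefinedDamageError):
            damage_score(prof)

    def test_living_population_scores_at_error_floor(self):
        spec = r.PopulationSpec("g", 60_000, 0.5, vitality="living",
                                damage=r.living_damage())
        genomes = r.generate_reference_genomes([spec], seed=15)
        frags = r.simulate_taphonomy(genomes["g"], spec, 0.0, seed=15,
                                     n_fragments=300)
        lib = r.sequence_library(
            frags, genomes,
            r.LibrarySpec("iDNA", False, read_length=100, target_depth=10.0,
                          block_prob=0.9, seq_error_rate=0.001, seed=15))
        sam_path = TestEndSymmetry._records(lib)
        prof = r.substitution_profile(sam_path, genomes)
        assert damage_score(prof) < 0.01


class TestDamageFit:
    @staticmethod
    def _profile_from(freqs, n=10_000):
        freqs = np.asarray(freqs, float)
        P = freqs.size
        opp = np.full(P, n, dtype=np.int64)
        ct = np.round(freqs * n).astype(np.int64)
        from relicdna.damage import DamageProfile
        return DamageProfile("g", "lib", P, ct, opp,
                             np.zeros(P, np.int64), np.zeros(P, np.int64))

    def test_noiseless_profile_recovered_exactly(self):
        p = np.arange(25)
        dss, dds, q = 0.3, 0.01, 0.6
        prof = self._profile_from(dds + (dss - dds) * q**p, n=10**9)
        fit = fit_damage_model(prof)
        assert fit.converged
        assert fit.delta_ss_hat == pytest.approx(dss, abs=1e-5)
        assert fit.delta_ds_hat == pytest.approx(dds, abs=1e-5)
        assert fit.q_hat == pytest.approx(q, abs=1e-4)

    def test_flat_profile_degenerate(self):
        fit = fit_damage_model(self._profile_from(np.full(25, 0.02), n=10**9))
        assert fit.degenerate
        assert fit.delta_ss_hat == pytest.approx(0.02, abs=1e-3)
        assert fit.delta_ds_hat == pytest.approx(0.02, abs=1e-3)

    def test_too_few_positions_rejected(self):
        with pytest.raises(ValueError):
            fit_damage_model(self._profile_from([0.3, 0.2, 0.1, 0.05]))

    def test_simulated_profile_shape_and_recovery(self, damage_sim_large):
        """Empirical profile follows the overhang-decay law (R^2 > 0.95)
        and the fit recovers the generating parameters."""
        prof = damage_sim_large["profile"]
        fit = fit_damage_model(prof)
        assert fit.converged
        assert fit.delta_ss_hat == pytest.approx(0.30, abs=0.03)
        assert fit.delta_ds_hat == pytest.approx(0.01, abs=0.01)
        assert fit.q_hat == pytest.approx(0.60, abs=0.05)
        y = prof.ct5
        r2 = 1.0 - fit.rss / np.sum((y - y.mean()) ** 2)
        assert r2 > 0.95


class TestRepairEffect:
    def test_repair_lowers_the_score(self):
        """score(repaired) <= score(unrepaired): full repair leaves only the
        sequencing-error floor."""
        spec = r.PopulationSpec("g", 40_000, 0.5, vitality="dead_intact",
                                damage=r.fossil_damage())
        genomes = r.generate_reference_genomes([spec], seed=16)
        frags = r.simulate_taphonomy(genomes["g"], spec, 1e5, seed=16,
                                     n_fragments=4000)
        scores = {}
        for repaired in (False, True):
            pool = r.apply_repair(frags, 1.0, seed=17) if repaired else frags
            lib = r.sequence_library(
                pool, genomes,
                r.LibrarySpec("iDNA", repaired, read_length=100,
                              target_depth=8.0, block_prob=0.9,
                              seq_error_rate=0.001, seed=16))
            prof = r.substitution_profile(TestEndSymmetry._records(lib),
                                          genomes)
            scores[repaired] = damage_score(prof)
        assert scores[True] <= scores[False]
        assert scores[False] / max(scores[True], 1e-6) >= 10
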