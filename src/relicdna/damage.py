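"""Position-specific mis-incorporation profiling of read alignments.

Measures the canonical ancient-DNA signature: the frequency of C->T
substitutions at each offset from the read 5' end (and the mirrored G->A
frequency from the 3' end), over the first ``max_pos`` positions.  Reverse-
strand alignments are flipped into read orientation first, so a reference-G
to read-A mismatch in genome coordinates counts as a 5' C->T on the read.

Only reference-C -> read-T observations enter the 5' numerator (not all
mismatches); soft-clipped bases and indel columns are excluded; overlapping
reads are counted independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io import open_alignments

__all__ = [
    "DamageProfile",
    "DamageFit",
    "UndefinedDamageError",
    "substitution_profile",
    "substitution_profiles",
    "damage_score",
    "fit_damage_model",
]


class UndefinedDamageError(ValueError):
    """Raised when a damage score is requested where no C was observed."""


@dataclass
class DamageProfile:
    """Terminal substitution frequencies for one genome x library.

    Arrays are indexed by 0-based offset; reported offsets are 1-based.
    Frequencies are NaN where no opportunity (reference C resp. G) was seen.
    """

    genome_id: str
    library_id: str
    max_pos: int
    ct_counts: np.ndarray
    opportunities5: np.ndarray
    ga_counts: np.ndarray
    opportunities3: np.ndarray

    @property
    def ct5(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.opportunities5 > 0,
                            self.ct_counts / self.opportunities5, np.nan)

    @property
    def ga3(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.opportunities3 > 0,
                            self.ga_counts / self.opportunities3, np.nan)

    def merge(self, other: "DamageProfile") -> "DamageProfile":
        """Pool counts with another profile (e.g. across bins of a library)."""
        if other.max_pos != self.max_pos:
            raise ValueError("profiles have different max_pos")
        gid = self.genome_id if self.genome_id == other.genome_id else "*pooled*"
        lid = self.library_id if self.library_id == other.library_id else "*pooled*"
        return DamageProfile(
            gid, lid, self.max_pos,
            self.ct_counts + other.ct_counts,
            self.opportunities5 + other.opportunities5,
            self.ga_counts + other.ga_counts,
            self.opportunities3 + other.opportunities3)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "offset": np.arange(1, self.max_pos + 1),
            "opportunities_ct": self.opportunities5,
            "ct_count": self.ct_counts,
            "ct_frequency": self.ct5,
            "opportunities_ga": self.opportunities3,
            "ga_count": self.ga_counts,
            "ga_frequency": self.ga3,
        })

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_COMP_U8 = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_U8[_a] = _b


def _tally_read(read, refseq: str, P: int, ct, opp5, ga, opp3) -> None:
    """General path: per-column tally via aligned pairs (handles indels)."""
    qseq = read.query_sequence
    L = len(qseq)
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        rb = refseq[rpos]
        qb = qseq[qpos]
        if read.is_reverse:
            off5 = L - 1 - qpos
            rb, qb = _COMP.get(rb, "N"), _COMP.get(qb, "N")
        else:
            off5 = qpos
        off3 = L - 1 - off5
        if off5 < P and rb == "C":
            opp5[off5] += 1
            if qb == "T":
                ct[off5] += 1
        if off3 < P and rb == "G":
            opp3[off3] += 1
            if qb == "A":
                ga[off3] += 1


def _tally_read_fast(read, ref_u8: np.ndarray, P: int, ct, opp5, ga, opp3) -> None:
    """Fast path for gapless (single-M CIGAR) alignments."""
    q = np.frombuffer(read.query_sequence.encode("ascii"), dtype=np.uint8)
    r = ref_u8[read.reference_start:read.reference_start + q.size]
    if read.is_reverse:
        q = _COMP_U8[q[::-1]]
        r = _COMP_U8[r[::-1]]
    n5 = min(P, q.size)
    q5, r5 = q[:n5], r[:n5]
    c5 = r5 == ord("C")
    np.add.at(opp5, np.flatnonzero(c5), 1)
    np.add.at(ct, np.flatnonzero(c5 & (q5 == ord("T"))), 1)
    q3, r3 = q[::-1][:n5], r[::-1][:n5]
    g3 = r3 == ord("G")
    np.add.at(opp3, np.flatnonzero(g3), 1)
    np.add.at(ga, np.flatnonzero(g3 & (q3 == ord("A"))), 1)


def substitution_profiles(alignments, references: Mapping[str, str],
                          max_pos: int = 25, min_mapq: int = 0,
                          library_id: str = "") -> dict[str, DamageProfile]:
    """Per-reference damage profiles from SAM records in a single pass.

    ``alignments`` may be a SAM path or an iterable of pysam records.
    Unmapped records are skipped; a record whose reference is absent from
    ``references`` is an error.
    """
    counts: dict[str, tuple] = {}
    ref_u8 = {g: np.frombuffer(s.encode("ascii"), dtype=np.uint8)
              for g, s in references.items()}
    for read in open_alignments(alignments):
        if read.is_unmapped or read.mapping_quality < min_mapq:
            continue
        rname = read.reference_name
        if rname not in references:
            raise KeyError(f"alignment reference {rname!r} not in references")
        if rname not in counts:
            counts[rname] = tuple(np.zeros(max_pos, dtype=np.int64)
                                  for _ in range(4))
        ct, opp5, ga, opp3 = counts[rname]
        cig = read.cigartuples
        if cig is not None and len(cig) == 1 and cig[0][0] == 0:
            _tally_read_fast(read, ref_u8[rname], max_pos, ct, opp5, ga, opp3)
        else:
            _tally_read(read, references[rname], max_pos, ct, opp5, ga, opp3)
    return {
        g: DamageProfile(g, library_id, max_pos, ct, opp5, ga, opp3)
        for g, (ct, opp5, ga, opp3) in counts.items()
    }


def substitution_profile(alignments, references: Mapping[str, str],
                         max_pos: int = 25, min_mapq: int = 0,
                         genome_id: str | None = None,
                         library_id: str = "") -> DamageProfile:
    """Damage profile pooled over all references (or one ``genome_id``).

    An empty alignment set yields an all-undefined profile (every frequency
    NaN), not an error.
    """
    per_ref = substitution_profiles(alignments, references, max_pos=max_pos,
                                    min_mapq=min_mapq, library_id=library_id)
    if genome_id is not None:
        if genome_id in per_ref:
            return per_ref[genome_id]
        z = np.zeros(max_pos, dtype=np.int64)
        return DamageProfile(genome_id, library_id, max_pos,
                             z, z.copy(), z.copy(), z.copy())
    if not per_ref:
        z = np.zeros(max_pos, dtype=np.int64)
        return DamageProfile("*pooled*", library_id, max_pos,
                             z, z.copy(), z.copy(), z.copy())
    profiles = list(per_ref.values())
    pooled = profiles[0]
    for p in profiles[1:]:
        pooled = pooled.merge(p)
    if len(profiles) > 1:
        pooled.genome_id = "*pooled*"
    return pooled


def damage_score(profile: DamageProfile) -> float:
    """Scalar damage score: the C->T frequency at 5' position 1."""
    if profile.opportunities5[0] == 0:
        raise UndefinedDamageError(
            f"no reference-C observed at 5' position 1 for "
            f"{profile.genome_id}/{profile.library_id}")
    return float(profile.ct_counts[0] / profile.opportunities5[0])


@dataclass
class DamageFit:
    """Parametric summary of a 5' C->T profile under the overhang-decay law."""

    delta_ss_hat: float
    delta_ds_hat: float
    q_hat: float
    rss: float
    converged: bool
    degenerate: bool = False  # amplitude ~0: q is unidentifiable

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def fit_damage_model(profile: DamageProfile) -> DamageFit:
    """Box-constrained least squares of ct5[p] ~ dds + (dss - dds) q^(p-1).

    Deterministic multistart over a fixed q grid; requires >= 5 defined
    positions.  A flat profile is reported with ``degenerate=True`` (the
    decay constant carries no information there).
    """
    freqs = profile.ct5
    defined = ~np.isnan(freqs)
    if defined.sum() < 5:
        raise ValueError("need >= 5 defined positions to fit the damage model")
    p = np.flatnonzero(defined).astype(float)  # 0-based offsets
    y = freqs[defined]

    def resid(x):
        dds, amp, q = x
        return dds + amp * q**p - y

    best = None
    for q0 in np.linspace(0.05, 0.95, 10):
        x0 = np.array([max(y.min(), 1e-4), max(y[0] - y.min(), 1e-4), q0])
        try:
            res = least_squares(resid, x0, bounds=([0, 0, 0], [1, 1, 0.999]))
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return DamageFit(float(y[0]), float(y.min()), 0.0,
                         float(np.sum((y - y.mean()) ** 2)), converged=False)
    dds, amp, q = best.x
    rss = float(2.0 * best.cost)
    return DamageFit(delta_ss_hat=float(min(dds + amp, 1.0)),
                     delta_ds_hat=float(dds), q_hat=float(q), rss=rss,
                     converged=bool(best.success),
                     degenerate=bool(amp < 1e-3))
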