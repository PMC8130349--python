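"""Shared fixtures: simulated scenarios reused across test modules.

All simulations are seeded; the heavyweight ones are session-scoped so the
damage-recovery and repair-contrast checks pay for them once.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

import relicdna as r
from relicdna.repair_assay import CompletenessRecord

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


FOSSIL_DELTA_SS = 0.3
FOSSIL_DELTA_DS = 0.01
FOSSIL_Q = 0.6


@pytest.fixture(scope="session")
def damage_sim_large(tmp_path_factory):
    """~1e5 reads from one heavily damaged genome (old-stratum regime)."""
    spec = r.PopulationSpec(
        "dmg1", 100_000, 0.5, vitality="dead_intact",
        damage=r.DamageParams(delta_ss=FOSSIL_DELTA_SS,
                              delta_ds=FOSSIL_DELTA_DS, q=FOSSIL_Q,
                              frag_mu=math.log(200.0), frag_sigma=0.4))
    genomes = r.generate_reference_genomes([spec], seed=11)
    frags = r.simulate_taphonomy(genomes["dmg1"], spec, age_yr=1e5, seed=11,
                                 n_fragments=100_000)
    lib = r.sequence_library(
        frags, genomes,
        r.LibrarySpec("iDNA", repaired=False, read_length=100,
                      target_depth=100.0, block_prob=0.0,
                      seq_error_rate=0.001, seed=11))
    sam = tmp_path_factory.mktemp("damage") / "large.sam"
    lib.write_sam(sam)
    profile = r.substitution_profile(sam, genomes, library_id="large")
    return {"spec": spec, "genomes": genomes, "fragments": frags,
            "library": lib, "sam": sam, "profile": profile}


@pytest.fixture(scope="session")
def living_regression():
    """Living-only multi-bin scenario: 15 intact populations on a depth
    ladder, repaired vs unrepaired completeness per bin."""
    depths = np.linspace(0.6, 3.0, 15)
    specs = [
        r.PopulationSpec(f"liv{i:02d}", 150_000, 0.5,
                         relative_abundance=float(d / depths.mean()),
                         vitality="living", damage=r.living_damage())
        for i, d in enumerate(depths)
    ]
    genomes = r.generate_reference_genomes(specs, seed=21)
    pool = []
    for spec in specs:
        pool.extend(r.simulate_taphonomy(genomes[spec.genome_id], spec,
                                         age_yr=26_000.0, seed=21))
    abundances = {s.genome_id: s.relative_abundance for s in specs}
    libs = {}
    for repaired in (False, True):
        frag_pool = r.apply_repair(pool, 1.0, seed=22) if repaired else pool
        libs[repaired] = r.sequence_library(
            frag_pool, genomes,
            r.LibrarySpec("iDNA", repaired=repaired, read_length=100,
                          target_depth=float(depths.mean()), block_prob=0.9,
                          seq_error_rate=0.001, seed=21),
            abundances=abundances)
    records = [
        CompletenessRecord(
            s.genome_id, "iDNA",
            r.completeness(libs[False].intervals(s.genome_id), 150_000),
            r.completeness(libs[True].intervals(s.genome_id), 150_000))
        for s in specs
    ]
    return {"specs": specs, "libraries": libs, "records": records}


@pytest.fixture(scope="session")
def fossil_contrast(tmp_path_factory):
    """20 heavily damaged bins sequenced with and without repair.

    delta_ss=0.3, blocker_rate=0.01/bp, pi=0.9, rho=1: blocking lesions
    starve the unrepaired library while full repair restores conversion."""
    damage = r.DamageParams(delta_ss=FOSSIL_DELTA_SS,
                            delta_ds=FOSSIL_DELTA_DS, q=FOSSIL_Q,
                            nick_rate=0.0, blocker_rate=0.01,
                            frag_mu=math.log(200.0), frag_sigma=0.5)
    specs = [
        r.PopulationSpec(f"fos{i:02d}", 50_000, 0.5, vitality="dead_intact",
                         damage=damage)
        for i in range(20)
    ]
    genomes = r.generate_reference_genomes(specs, seed=31)
    pool = []
    for spec in specs:
        pool.extend(r.simulate_taphonomy(genomes[spec.genome_id], spec,
                                         age_yr=1e5, seed=31))
    libs = {}
    sams = {}
    tmp = tmp_path_factory.mktemp("fossil")
    for repaired in (False, True):
        frag_pool = r.apply_repair(pool, 1.0, seed=32) if repaired else pool
        lib = r.sequence_library(
            frag_pool, genomes,
            r.LibrarySpec("iDNA", repaired=repaired, read_length=100,
                          target_depth=10.0, block_prob=0.9,
                          seq_error_rate=0.001, seed=31))
        libs[repaired] = lib
        sam = tmp / f"fossil_{'rep' if repaired else 'unrep'}.sam"
        lib.write_sam(sam)
        sams[repaired] = sam
    records = [
        CompletenessRecord(
            s.genome_id, "iDNA",
            r.completeness(libs[False].intervals(s.genome_id), 50_000),
            r.completeness(libs[True].intervals(s.genome_id), 50_000))
        for s in specs
    ]
    return {"specs": specs, "genomes": genomes, "libraries": libs,
            "sams": sams, "records": records}
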