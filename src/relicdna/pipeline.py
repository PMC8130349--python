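"""Scenario orchestration: simulate -> profile -> assay -> classify -> report.

``run_scenario`` executes the full chain for one validated scenario config
and writes every artifact (FASTA/FASTQ/SAM/TSV/JSON) plus a manifest with
seeds and checksums.  Outputs are assembled in a ``.partial`` staging
directory and renamed into place on success, so a failed run leaves no
half-written bundle.  Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import math
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as _io
from ._rng import child_rng
from .classify import (BinEvidence, FractionEvidence, PaleoecologicalCall,
                       classify_population, summarize_assemblage)
from .config import ScenarioConfig
from .damage import (DamageProfile, UndefinedDamageError, damage_score,
                     substitution_profiles)
from .growth import coverage_profile, grid_index, growth_table
from .racemization import racemization_report
from .repair_assay import (CompletenessRecord, completeness, library_stats,
                           repair_gain_regression)
from .simulate import (SequencedLibrary, apply_repair, generate_reference_genomes,
                       partition_idna_edna, sequence_library, simulate_taphonomy)

__all__ = ["ScenarioResult", "run_scenario", "simulate_scenario"]


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    outdir: Path
    genomes: dict[str, str]
    libraries: dict[str, SequencedLibrary]
    completeness_records: list[CompletenessRecord]
    comparisons: dict[str, dict]
    evidence: list[BinEvidence]
    calls: list[PaleoecologicalCall]
    summary: dict
    manifest: dict = field(default_factory=dict)

    @property
    def truth_vitality(self) -> dict[str, str]:
        return {p.genome_id: p.vitality for p in self.config.populations}


def simulate_scenario(cfg: ScenarioConfig
                      ) -> tuple[dict[str, str], dict[str, SequencedLibrary]]:
    """Generate genomes, run taphonomy/partition/repair and sequence the
    2x2 library grid.  Returns (genomes, libraries by library_id)."""
    specs = cfg.population_specs()
    genomes = generate_reference_genomes(specs, cfg.seed)
    abundances = {p.genome_id: p.relative_abundance for p in cfg.populations}

    pools: dict[str, list] = {"iDNA": [], "eDNA": []}
    for spec, pcfg in zip(specs, cfg.populations):
        mean_len = math.exp(spec.damage.frag_mu
                            + 0.5 * spec.damage.frag_sigma**2)
        n_frag = max(100, int(round(cfg.pool_coverage * spec.genome_length
                                    / mean_len)))
        frags = simulate_taphonomy(genomes[spec.genome_id], spec,
                                   age_yr=pcfg.age_yr, seed=cfg.seed,
                                   n_fragments=n_frag)
        pseed = int(child_rng(cfg.seed, "partition-seed",
                              spec.genome_id).integers(2**31))
        idna, edna = partition_idna_edna(frags, spec.vitality,
                                         leakage=pcfg.leakage, seed=pseed)
        pools["iDNA"].extend(idna)
        pools["eDNA"].extend(edna)

    libraries: dict[str, SequencedLibrary] = {}
    for libspec in cfg.library_specs():
        pool = pools[libspec.fraction]
        if libspec.repaired:
            rseed = int(child_rng(cfg.seed, "repair-seed",
                                  libspec.library_id).integers(2**31))
            pool = apply_repair(pool, libspec.repair_efficiency, seed=rseed)
        if pool:
            lib = sequence_library(pool, genomes, libspec,
                                   abundances=abundances)
        else:
            lib = SequencedLibrary(libspec, [], pd.DataFrame(),
                                   {g: len(s) for g, s in genomes.items()})
        libraries[libspec.library_id] = lib
    return genomes, libraries


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_scenario(cfg: ScenarioConfig, outdir) -> ScenarioResult:
    """Run the full pipeline and write the result bundle under ``outdir``."""
    outdir = Path(outdir)
    staging = outdir.parent / (outdir.name + ".partial")
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir(parents=True)
    try:
        result = _run_into(cfg, staging)
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    if outdir.exists():
        shutil.rmtree(outdir)
    staging.rename(outdir)
    result.outdir = outdir
    return result


def _run_into(cfg: ScenarioConfig, out: Path) -> ScenarioResult:
    genomes, libraries = simulate_scenario(cfg)
    _io.write_fasta(genomes, out / "references.fasta")

    lib_stats = {}
    for lib_id, lib in libraries.items():
        lib.write_fastq(out / f"{lib_id}.fastq")
        lib.write_sam(out / f"{lib_id}.sam")
        lib.truth.to_csv(out / f"{lib_id}.truth.tsv", sep="\t", index=False)
        lib_stats[lib_id] = library_stats(lib)

    # damage profiles per genome x library (read back from the SAM files)
    profiles: dict[str, dict[str, DamageProfile]] = {}
    profile_frames = []
    for lib_id in libraries:
        per_ref = substitution_profiles(out / f"{lib_id}.sam", genomes,
                                        library_id=lib_id)
        profiles[lib_id] = per_ref
        for gid, prof in per_ref.items():
            frame = prof.to_frame()
            frame.insert(0, "library_id", lib_id)
            frame.insert(0, "genome_id", gid)
            profile_frames.append(frame)
    if profile_frames:
        pd.concat(profile_frames).to_csv(out / "damage_profiles.tsv",
                                         sep="\t", index=False, na_rep="NA")

    # completeness per bin x fraction and the 1:1-line comparison
    records: list[CompletenessRecord] = []
    evidence: list[BinEvidence] = []
    rows = []
    for pop in cfg.populations:
        gid = pop.genome_id
        G = pop.genome_length
        frac_evidence = {}
        for fraction in ("iDNA", "eDNA"):
            unrep = libraries[f"{fraction}_unrepaired"]
            rep = libraries[f"{fraction}_repaired"]
            iv_u = unrep.intervals(gid)
            iv_r = rep.intervals(gid)
            present = bool(iv_u or iv_r)
            comp_u = completeness(iv_u, G) if iv_u else 0.0
            comp_r = completeness(iv_r, G) if iv_r else 0.0
            depth_u = sum(e - s for s, e in iv_u) / G
            depth_r = sum(e - s for s, e in iv_r) / G

            def _score(lib_id):
                prof = profiles.get(lib_id, {}).get(gid)
                if prof is None:
                    return None
                try:
                    return damage_score(prof)
                except UndefinedDamageError:
                    return None

            dmg_u = _score(f"{fraction}_unrepaired")
            dmg_r = _score(f"{fraction}_repaired")
            frac_evidence[fraction] = FractionEvidence(
                present=present, damage_unrepaired=dmg_u,
                damage_repaired=dmg_r,
                delta_completeness=comp_r - comp_u)
            if present:
                records.append(CompletenessRecord(
                    bin_id=gid, fraction=fraction,
                    completeness_unrepaired=comp_u,
                    completeness_repaired=comp_r,
                    mean_depth_unrepaired=depth_u,
                    mean_depth_repaired=depth_r))
            rows.append({"bin_id": gid, "fraction": fraction,
                         "present": present,
                         "completeness_unrepaired": comp_u,
                         "completeness_repaired": comp_r,
                         "delta_completeness": comp_r - comp_u,
                         "damage_unrepaired": dmg_u,
                         "damage_repaired": dmg_r})
        evidence.append(BinEvidence(bin_id=gid,
                                    idna=frac_evidence["iDNA"],
                                    edna=frac_evidence["eDNA"]))
    pd.DataFrame(rows).to_csv(out / "bin_evidence.tsv", sep="\t",
                              index=False, na_rep="NA")

    comparisons: dict[str, dict] = {}
    for fraction in ("iDNA", "eDNA"):
        frecs = [r for r in records if r.fraction == fraction]
        if len(frecs) >= 3:
            cmp_ = repair_gain_regression(frecs)
            comparisons[fraction] = {
                "slope": cmp_.slope, "intercept": cmp_.intercept,
                "pearson_r": cmp_.pearson_r, "n_bins": cmp_.n_bins,
                "mean_delta": cmp_.mean_delta, "x_constant": cmp_.x_constant}
        else:
            comparisons[fraction] = {"n_bins": len(frecs),
                                     "note": "too few bins for regression"}
    with open(out / "repair_comparison.json", "w") as fh:
        json.dump(comparisons, fh, indent=2, sort_keys=True)

    # growth index from the repaired iDNA coverage, ori/ter loci as checks
    grid_results = []
    rep_idna = libraries["iDNA_repaired"]
    for pop in cfg.populations:
        if pop.genome_length < cfg.grid_bin_size:
            continue
        iv = rep_idna.intervals(pop.genome_id)
        if not iv:
            continue
        prof = coverage_profile(iv, pop.genome_length,
                                bin_size=cfg.grid_bin_size,
                                smoothing_window=cfg.grid_smoothing,
                                genome_id=pop.genome_id)
        ter = pop.ter_position
        if ter is None:
            ter = (pop.ori_position + pop.genome_length // 2) % pop.genome_length
        grid_results.append(grid_index(prof, dnaA_pos=pop.ori_position,
                                       dif_pos=ter))
    if grid_results:
        growth_table(grid_results).to_csv(out / "growth_index.tsv", sep="\t",
                                          index=False, na_rep="NA")

    # racemization clock report
    if cfg.racemization is not None and cfg.racemization.ages:
        rep = racemization_report(cfg.racemization.observations,
                                  cfg.racemization.ages,
                                  cfg.racemization.to_params(),
                                  dl0=cfg.racemization.dl0)
        rep.to_csv(out / "racemization.tsv", sep="\t", index=False)

    # classification
    thresholds = cfg.thresholds.to_thresholds()
    calls = [classify_population(e, thresholds) for e in evidence]
    truth = {p.genome_id: p.vitality for p in cfg.populations}
    summary = summarize_assemblage(calls, ground_truth=truth)
    pd.DataFrame([{"bin_id": c.bin_id, "label": c.label,
                   "rationale": "; ".join(c.rationale)} for c in calls]
                 ).to_csv(out / "calls.tsv", sep="\t", index=False)
    summary_json = {
        "n_bins": summary["n_bins"],
        "label_counts": summary["label_counts"],
        "accuracy": summary.get("accuracy"),
        "library_stats": lib_stats,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary_json, fh, indent=2, sort_keys=True, default=str)

    manifest = {
        "seed": cfg.seed,
        "config": cfg.model_dump(),
        "artifacts": {p.name: _sha256(p)
                      for p in sorted(out.iterdir()) if p.is_file()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return ScenarioResult(config=cfg, outdir=out, genomes=genomes,
                          libraries=libraries,
                          completeness_records=records,
                          comparisons=comparisons, evidence=evidence,
                          calls=calls, summary=summary, manifest=manifest)
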