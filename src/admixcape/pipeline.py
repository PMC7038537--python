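"""End-to-end orchestration of the synthetic admixture-characterization
study: simulate -> QC -> ancestry proportions -> f-statistics -> LSBL and
haplotype scans -> RoH -> shared private alleles -> weighted-LD dating ->
report.

The default configuration states the world the pipeline emulates: a
predominantly European admixed cohort (proportions 95.3 / 1.7 / 1.3 / 0.9
/ 0.8 percent across five continental sources) formed by a single pulse
9.3 generations before sampling, genotyped on one 2-Morgan chromosome.

Every stage writes TSV artifacts into the output directory plus a compact
``stage_<name>.json``; the final report is assembled from those stage
files, so re-running with an identical configuration (same config hash in
the manifest) skips completed stages and reproduces a byte-identical
report.  One global seed fans out to per-stage child seeds by stable
hashing of stage names.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import admixdate, admixprop, fstats, genio, haploscan, lsblscan, privshare, rohcall
from . import simcohort as sc
from .genio import GenotypeError


@dataclass
class PipelineConfig:
    """Fully materialized pipeline configuration (all defaults explicit)."""

    # scenario
    source_names: tuple[str, ...] = ("EUR", "SAS", "KHS", "EAS", "WAF")
    source_fst: tuple[float, ...] = (0.10, 0.10, 0.20, 0.12, 0.15)
    source_n: tuple[int, ...] = (80, 80, 80, 80, 80)
    proportions: tuple[float, ...] = (0.953, 0.017, 0.013, 0.009, 0.008)
    generations_ago: float = 9.3
    n_admixed: int = 200
    n_snps: int = 20000
    chromosome_length_morgans: float = 2.0
    # QC
    snp_missing_max: float = 0.10
    ind_missing_max: float = 0.15
    hwe_alpha: float = 0.001
    relatedness_threshold: float = 0.25
    # statistics
    jackknife_block_cm: float = 5.0
    lsbl_refs: tuple[str, str] = ("EUR", "SAS")
    lsbl_top_n: int = 5
    lsbl_merge_window_bp: int = 500_000
    xpehh_ref: str = "EUR"
    privshare_pair: tuple[str, str] = ("ADMIX", "EUR")
    privshare_g_max: int = 20
    dating_refs: tuple[str, str] = ("EUR", "KHS")
    generation_time_years: float = 30.0
    reference_birth_year: float = 1960.0
    ancestor_generations: int = 11
    # bookkeeping
    target_name: str = "ADMIX"
    outdir: str = "admixcape_out"
    seed: int = 1
    log_level: str = "info"

    def __post_init__(self) -> None:
        k = len(self.source_names)
        if not (len(self.source_fst) == len(self.source_n) == len(self.proportions) == k):
            raise GenotypeError("source_names, source_fst, source_n, proportions must align")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise GenotypeError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {
            k: tuple(v) if isinstance(getattr(cls, k, None), tuple) or isinstance(v, list) else v
            for k, v in d.items()
        }
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def scenario(self) -> sc.AdmixtureScenario:
        specs = tuple(
            sc.SourcePopSpec(n, f, s)
            for n, f, s in zip(self.source_names, self.source_fst, self.source_n)
        )
        return sc.AdmixtureScenario(
            sources=specs,
            proportions=self.proportions,
            generations_ago=self.generations_ago,
            n_admixed=self.n_admixed,
            n_snps=self.n_snps,
            chromosome_length_morgans=self.chromosome_length_morgans,
            admixed_name=self.target_name,
            seed=stage_seed(self.seed, "simulate"),
        )


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed below 2^31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


class _StageRunner:
    def __init__(self, outdir: Path, config_hash: str, log: list[str]):
        self.outdir = outdir
        self.config_hash = config_hash
        self.log = log
        manifest = outdir / "manifest.json"
        self.cache_valid = (
            manifest.exists()
            and json.loads(manifest.read_text()).get("config_hash") == config_hash
        )

    def run(self, name: str, fn) -> dict:
        path = self.outdir / f"stage_{name}.json"
        if self.cache_valid and path.exists():
            self.log.append(f"stage {name}: cached")
            return json.loads(path.read_text())
        try:
            result = _round_floats(fn())
        except Exception as exc:  # preserve partial artifacts, name the stage
            raise GenotypeError(f"stage {name!r} failed: {exc}") from exc
        path.write_text(json.dumps(result, sort_keys=True, indent=1))
        self.log.append(f"stage {name}: computed")
        return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic replica and return the structured report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    runner = _StageRunner(outdir, config.config_hash(), log)
    config.to_yaml(outdir / "config.yaml")

    # --- simulate (always regenerated: cheap and deterministic) -----------
    scen = config.scenario()
    cohort = sc.simulate_cohort(scen)
    sc.write_cohort(cohort, outdir, "cohort")
    sim_info = runner.run(
        "simulate",
        lambda: {
            "n_samples": cohort.genotypes.n_samples,
            "n_snps": cohort.genotypes.n_snps,
            "truth_mean_q": {
                k: float(v) for k, v in cohort.truth_q.mean().items()
            },
        },
    )
    gm = cohort.genotypes
    sources = list(config.source_names)
    target = config.target_name
    cfg_jk = fstats.JackknifeConfig(block_size_cm=config.jackknife_block_cm)

    # --- qc ---------------------------------------------------------------
    def _qc():
        filtered, rep = genio.qc_filter(
            gm,
            snp_missing_max=config.snp_missing_max,
            ind_missing_max=config.ind_missing_max,
            hwe_alpha=config.hwe_alpha,
            hwe_per_population=True,
        )
        rep.to_frame().to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        (outdir / "qc_log.txt").write_text("\n".join(rep.log) + ("\n" if rep.log else ""))
        return {
            "n_snps_in": gm.n_snps,
            "n_snps_out": filtered.n_snps,
            "n_removed_hwe": rep.n_removed_hwe,
            "n_removed_missingness": rep.n_removed_missingness,
            "samples_removed": rep.samples_removed,
        }

    qc_info = runner.run("qc", _qc)
    gm_qc, _ = genio.qc_filter(
        gm,
        snp_missing_max=config.snp_missing_max,
        ind_missing_max=config.ind_missing_max,
        hwe_alpha=config.hwe_alpha,
    )

    # --- ancestry proportions --------------------------------------------
    def _qest():
        qm = admixprop.supervised_admixture(gm_qc, target, sources, max_iter=6000)
        qm.q.to_csv(outdir / "qmatrix.tsv", sep="\t")
        groups = {
            "non_european": [s for s in sources if s != "EUR"],
            "african": [s for s in sources if s in ("KHS", "WAF")],
            "asian": [s for s in sources if s in ("SAS", "EAS")],
        }
        groups = {k: v for k, v in groups.items() if v}
        summary = admixprop.summarize_ancestry(qm, groups, bin_group="non_european")
        summary["grouped"].to_csv(outdir / "grouped_ancestry.tsv", sep="\t")
        summary["group_stats"].to_csv(outdir / "group_stats.tsv", sep="\t")
        truth_err = (
            (qm.q - cohort.truth_q.loc[qm.q.index]).abs().mean().mean()
            if set(qm.q.index) <= set(cohort.truth_q.index)
            else None
        )
        return {
            "component_means": {k: float(v) for k, v in summary["means"].items()},
            "group_means": {k: float(v) for k, v in summary["group_stats"]["mean"].items()},
            "group_sds": {k: float(v) for k, v in summary["group_stats"]["sd"].items()},
            "bins": {k: float(v) for k, v in summary["bins"].items()},
            "mean_abs_error_vs_truth": truth_err,
        }

    qest_info = runner.run("qest", _qest)

    # --- f-statistics -----------------------------------------------------
    def _fstats():
        screen = fstats.f3_screen(gm_qc, target, sources, cfg_jk)
        screen.to_csv(outdir / "f3_screen.tsv", sep="\t", index=False)
        best = screen.iloc[0]
        f4 = fstats.f4_test(gm_qc, target, sources[0], sources[2], sources[1], cfg_jk)
        return {
            "f3_best_pair": [best["source_a"], best["source_b"]],
            "f3_best_z": float(best["z"]),
            "f4_example": {"pops": list(f4.pops), "value": f4.value, "z": f4.z},
        }

    fstat_info = runner.run("fstats", _fstats)

    # --- LSBL -------------------------------------------------------------
    def _lsbl():
        track = lsblscan.lsbl_scan(gm_qc, target, *config.lsbl_refs)
        track.to_csv(outdir / "lsbl_track.tsv", sep="\t", index=False)
        peaks = lsblscan.call_peaks(
            track, top_n=config.lsbl_top_n, merge_window_bp=config.lsbl_merge_window_bp
        )
        lsblscan.peaks_to_frame(peaks).to_csv(outdir / "lsbl_peaks.tsv", sep="\t", index=False)
        return {
            "mean_lsbl": float(np.nanmean(track["lsbl"])),
            "peaks": [
                {"chrom": p.chrom, "apex_pos": p.apex_pos, "apex_value": p.apex_value}
                for p in peaks
            ],
        }

    lsbl_info = runner.run("lsbl", _lsbl)

    # --- haplotype scans --------------------------------------------------
    hap_variants = gm.variants
    hapset = {
        pop: haploscan.HaplotypeSet(
            cohort.haplotypes[np.repeat(gm.sample_mask(pop), 2)],
            hap_variants["pos"].to_numpy(),
            hap_variants["cm"].to_numpy(),
        )
        for pop in (target, config.xpehh_ref)
    }

    def _haplo():
        # simulator convention: the ref allele is the ancestral state
        anc = pd.DataFrame({"ancestral": hap_variants["ref"], "n_outgroups_agreeing": 4})
        ihs = haploscan.ihs_scan(hapset[target], anc, hap_variants)
        ihs.to_csv(outdir / "ihs.tsv", sep="\t", index=False)
        xp = haploscan.xpehh_scan(hapset[target], hapset[config.xpehh_ref])
        xp.to_csv(outdir / "xpehh.tsv", sep="\t", index=False)
        s = ihs["ihs_std"].dropna()
        return {
            "ihs_n_scored": int(s.size),
            "ihs_frac_abs_gt2": float((s.abs() > 2).mean()) if s.size else None,
            "xpehh_n_scored": int(xp["xpehh_std"].notna().sum()),
        }

    haplo_info = runner.run("haploscan", _haplo)

    # --- RoH --------------------------------------------------------------
    def _roh():
        segments = []
        for sid in gm_qc.samples.index:
            segments += rohcall.call_roh(gm_qc, sid)
        rohcall.segments_to_frame(segments).to_csv(outdir / "roh_segments.tsv", sep="\t", index=False)
        per_ind, per_pop = rohcall.summarize_roh(segments, gm_qc.samples)
        per_ind.to_csv(outdir / "roh_per_individual.tsv", sep="\t")
        per_pop.to_csv(outdir / "roh_per_population.tsv", sep="\t")
        return {
            "n_segments": len(segments),
            "mean_total_kb": {
                pop: float(per_ind.loc[per_ind["population"] == pop, "total_kb"].mean())
                for pop in gm_qc.populations()
            },
        }

    roh_info = runner.run("roh", _roh)

    # --- shared private alleles ------------------------------------------
    def _privshare():
        pa, pb = config.privshare_pair
        others = [p for p in gm_qc.populations() if p not in (pa, pb)]
        curve = privshare.shared_private_alleles(gm_qc, pa, pb, others, config.privshare_g_max)
        curve.to_frame().to_csv(outdir / "shared_private.tsv", sep="\t", index=False)
        return {
            "pair": [pa, pb],
            "g_max": config.privshare_g_max,
            "mean_at_gmax": float(curve.mean_shared_private[-1]),
        }

    priv_info = runner.run("privshare", _privshare)

    # --- dating -----------------------------------------------------------
    def _dating():
        r1, r2 = config.dating_refs
        curve = admixdate.weighted_ld_curve(gm_qc, target, r1, r2)
        curve.to_frame().to_csv(outdir / "weighted_ld.tsv", sep="\t", index=False)
        fit = admixdate.fit_decay(curve)
        out = {"refs": [r1, r2], "status": fit.status}
        if fit.status == "ok":
            years_ago, calendar = admixdate.admixture_calendar(
                fit.generations, config.generation_time_years, config.reference_birth_year
            )
            out.update(
                generations=fit.generations,
                amplitude=fit.amplitude,
                years_ago=years_ago,
                calendar_year=calendar,
            )
            non_eur = [s for s in sources if s != "EUR"]
            means = qest_info["component_means"]
            out["ancestor_equivalents"] = {
                s: admixdate.ancestor_equivalents(means[s], config.ancestor_generations)[1]
                for s in non_eur
            }
            out["ancestor_slots"] = 2 ** config.ancestor_generations
        return out

    dating_info = runner.run("dating", _dating)

    report = {
        "config_hash": config.config_hash(),
        "simulate": sim_info,
        "qc": qc_info,
        "ancestry": qest_info,
        "fstats": fstat_info,
        "lsbl": lsbl_info,
        "haploscan": haplo_info,
        "roh": roh_info,
        "privshare": priv_info,
        "dating": dating_info,
    }
    (outdir / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    (outdir / "manifest.json").write_text(
        json.dumps({"config_hash": config.config_hash()}, sort_keys=True)
    )
    (outdir / "pipeline_log.txt").write_text("\n".join(log) + "\n")
    return report
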