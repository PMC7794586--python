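"""End-to-end replay of the fine-mapping analysis chain on synthetic cohorts.

Stages mirror the order of a trans-ancestral fine-mapping study: simulate
per-ancestry cohorts over a shared marker map -> QC -> additive logistic
scan with admixture covariates -> stepwise conditional analysis ->
approximate-Bayes-factor fine-mapping with 95% credible sets per ancestry
-> cross-ancestry credible-set intersection -> sample-size-weighted
Z meta-analysis -> fine-mapping of the meta-analysis from p-values.

Every stage writes a TSV stamped with the seed, and the run is
deterministic given the config and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, finemap, meta, qc
from .io import write_table, write_vcf
from .synthgen import AncestrySpec, simulate_case_control, simulate_haplotype_panel

__all__ = ["AncestryConfig", "RunConfig", "RunReport", "run_pipeline"]

DEFAULT_ANCESTRIES = ("EU", "AA", "AS", "AI")


@dataclass
class AncestryConfig:
    name: str
    n_cases: int = 500
    n_controls: int = 500
    ld_rho: float = 0.5
    maf_low: float = 0.1
    maf_high: float = 0.5


@dataclass
class RunConfig:
    """Everything `run_pipeline` needs; round-trips losslessly through YAML."""

    seed: int = 1
    out_dir: str = "crediblemap_run"
    n_variants: int = 60
    causal_index: int = 30
    position_spacing: int = 1000
    or_per_allele: float = 1.35
    base_rate: float = 0.2
    admixture_effect: list[float] = field(default_factory=lambda: [0.5, -0.5, 0.0])
    missing_rate: float = 0.02
    n_hap_factor: int = 4
    ancestries: list[AncestryConfig] = field(
        default_factory=lambda: [AncestryConfig(name=n) for n in DEFAULT_ANCESTRIES]
    )
    maf_min: float = 0.01
    call_rate_min: float = 0.90
    sample_call_rate_min: float = 0.95
    pihat_max: float = 0.4
    r2_min: float = 0.8
    relatedness: bool = False
    p_stop: float = 1e-4
    p_report_hi: float = 1e-2
    prior_w: float = 0.04
    level: float = 0.95
    write_vcfs: bool = False

    def __post_init__(self) -> None:
        self.ancestries = [
            a if isinstance(a, AncestryConfig) else AncestryConfig(**a)
            for a in self.ancestries
        ]
        if not 0 < self.level <= 1:
            raise ValueError("level must lie in (0, 1]")
        if self.prior_w < 0:
            raise ValueError("prior_w must be non-negative")
        if not 0 <= self.causal_index < self.n_variants:
            raise ValueError("causal_index out of range")
        for thr, lo, hi in (
            (self.maf_min, 0, 0.5),
            (self.call_rate_min, 0, 1),
            (self.sample_call_rate_min, 0, 1),
            (self.pihat_max, 0, 1),
            (self.r2_min, 0, 1),
        ):
            if not lo <= thr <= hi:
                raise ValueError(f"threshold {thr} outside [{lo}, {hi}]")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class RunReport:
    out_dir: Path
    shared_credible_variants: list[str]
    credible_set_sizes: dict[str, int]
    causal_id: str
    top_meta_variant: str
    top_meta_p: float
    summary_path: Path


def run_pipeline(config: RunConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    stamp = {"seed": config.seed, "tool": "crediblemap"}

    root = np.random.SeedSequence(config.seed)
    freq_seed, *ancestry_seeds = root.spawn(1 + len(config.ancestries))
    freq_rng = np.random.default_rng(freq_seed)
    positions = np.arange(1, config.n_variants + 1) * config.position_spacing
    variant_ids = None
    causal_id = f"snp_{config.causal_index + 1}"

    per_ancestry: dict[str, dict] = {}
    credible_sets: dict[str, finemap.CredibleSet] = {}
    study_frames: list[pd.DataFrame] = []
    maf_by_ancestry: dict[str, pd.Series] = {}

    for a_cfg, a_seed in zip(config.ancestries, ancestry_seeds):
        try:
            stage = "simulate"
            freqs = freq_rng.uniform(a_cfg.maf_low, a_cfg.maf_high, config.n_variants)
            spec = AncestrySpec(
                name=a_cfg.name,
                n_variants=config.n_variants,
                alt_freqs=freqs,
                ld_rho=a_cfg.ld_rho,
                positions=positions,
                n_cases=a_cfg.n_cases,
                n_controls=a_cfg.n_controls,
            )
            child = np.random.default_rng(a_seed)
            panel_seed, cohort_seed = child.integers(0, 2**31 - 1, size=2)
            n_hap = 2 * config.n_hap_factor * (a_cfg.n_cases + a_cfg.n_controls)
            panel = simulate_haplotype_panel(spec, n_hap=n_hap, seed=int(panel_seed))
            cohort = simulate_case_control(
                panel,
                causal_index=config.causal_index,
                or_per_allele=config.or_per_allele,
                base_rate=config.base_rate,
                admixture_effect=np.asarray(config.admixture_effect),
                missing_rate=config.missing_rate,
                seed=int(cohort_seed),
            )
            g = cohort.to_genotype_matrix()
            variant_ids = g.variant_ids
            if config.write_vcfs:
                write_vcf(g, out / f"genotypes_{a_cfg.name}.vcf")

            stage = "qc"
            g_clean, report = qc.run_qc(
                g,
                maf_min=config.maf_min,
                call_rate_min=config.call_rate_min,
                sample_call_rate_min=config.sample_call_rate_min,
                pihat_max=config.pihat_max,
                r2_min=config.r2_min,
                relatedness=config.relatedness,
            )
            write_table(report.to_frame(), out / f"qc_{a_cfg.name}.tsv", stamp)
            kept = np.isin(np.array([str(s) for s in g.sample_ids], dtype=object),
                           g_clean.sample_ids)
            status = cohort.status[kept]
            covar = cohort.admixture[kept]

            stage = "assoc"
            records = assoc.logistic_scan(g_clean, status, covariates=covar)
            scan = assoc.assoc_frame(g_clean, records)
            scan.insert(0, "GROUP", a_cfg.name)
            write_table(scan, out / f"assoc_{a_cfg.name}.tsv", stamp)

            stage = "conditional"
            trace = assoc.conditional_stepwise(
                g_clean,
                status,
                covariates=covar,
                p_stop=config.p_stop,
                p_report_hi=config.p_report_hi,
            )
            trace_rows = [
                {
                    "step": i,
                    "conditioned_on": ",".join(s.conditioned_on) or ".",
                    "top_variant": s.top_variant or ".",
                    "top_p": s.top_p,
                    "n_below_stop": len(s.below_stop),
                    "residual_window": ",".join(s.residual_window) or ".",
                }
                for i, s in enumerate(trace.steps)
            ]
            write_table(
                pd.DataFrame(trace_rows), out / f"conditional_{a_cfg.name}.tsv", stamp
            )

            stage = "finemap"
            ok = scan[scan["CONVERGED"]].reset_index(drop=True)
            table, cs = finemap.finemap_region(
                ids=ok["ID"].to_numpy(),
                beta=ok["BETA"].to_numpy(),
                se=ok["SE"].to_numpy(),
                prior_w=config.prior_w,
                level=config.level,
            )
            write_table(table, out / f"finemap_{a_cfg.name}.tsv", stamp)
            write_table(
                pd.DataFrame(
                    {"ID": cs.members, "PP": cs.member_pps, "LEVEL": config.level}
                ),
                out / f"credible_set_{a_cfg.name}.tsv",
                stamp,
            )
            credible_sets[a_cfg.name] = cs

            maf = pd.Series(g_clean.maf(), index=g_clean.variant_ids)
            maf_by_ancestry[a_cfg.name] = maf
            study = ok[["ID", "A1", "A2", "BETA", "P", "N"]].copy()
            study_frames.append(study)
            per_ancestry[a_cfg.name] = {
                "n_variants_post_qc": g_clean.n_variants,
                "n_samples_post_qc": g_clean.n_samples,
                "conditional_steps": trace.n_signals,
                "credible_set_size": len(cs),
            }
        except Exception as err:  # pragma: no cover - abort path
            raise RuntimeError(
                f"pipeline stage '{stage}' failed for ancestry {a_cfg.name}: {err}"
            ) from err

    shared = finemap.shared_credible_variants(credible_sets)
    write_table(
        pd.DataFrame({"ID": shared}) if shared else pd.DataFrame(columns=["ID"]),
        out / "shared_credible_variants.tsv",
        stamp,
    )

    meta_records, skipped = meta.weighted_z_meta(study_frames)
    meta_df = meta.meta_frame(meta_records)
    write_table(meta_df, out / "meta.tsv", stamp)
    if len(skipped):
        write_table(skipped, out / "meta_skipped.tsv", stamp)

    # trans-ancestral credible set from meta p-values
    maf_all = pd.concat(maf_by_ancestry, axis=1).mean(axis=1)
    meta_map = meta_df.set_index("ID")
    usable = [v for v in meta_map.index if v in maf_all.index]
    meta_table, meta_cs = finemap.finemap_region(
        ids=np.array(usable, dtype=object),
        p=meta_map.loc[usable, "P"].to_numpy(),
        n=meta_map.loc[usable, "N_TOTAL"].to_numpy(),
        maf=maf_all.loc[usable].to_numpy(),
        prior_w=config.prior_w,
        level=config.level,
    )
    write_table(meta_table, out / "finemap_meta.tsv", stamp)
    write_table(
        pd.DataFrame(
            {"ID": meta_cs.members, "PP": meta_cs.member_pps, "LEVEL": config.level}
        ),
        out / "credible_set_meta.tsv",
        stamp,
    )

    top = meta_df.loc[meta_df["P"].idxmin()]
    summary = {
        "seed": config.seed,
        "causal_id": causal_id,
        "shared_credible_variants": shared,
        "credible_set_sizes": {k: len(v) for k, v in credible_sets.items()},
        "meta_credible_set_size": len(meta_cs),
        "top_meta_variant": str(top["ID"]),
        "top_meta_p": float(top["P"]),
        "per_ancestry": per_ancestry,
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return RunReport(
        out_dir=out,
        shared_credible_variants=shared,
        credible_set_sizes={k: len(v) for k, v in credible_sets.items()},
        causal_id=causal_id,
        top_meta_variant=str(top["ID"]),
        top_meta_p=float(top["P"]),
        summary_path=summary_path,
    )
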