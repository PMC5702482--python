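"""End-to-end orchestration: config, per-stage seeding, artifact bundle.

A run either simulates a cohort or loads PED/MAP + FAM files, then applies
QC, PCA with sign orientation, spouse-pair extraction, per-stratum
correlation tables (including an exclude-site variant), the random
within-ethnicity pairing null, and a manifest with config hash and seeds.
All tabular outputs are TSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .nulldist import compare_observed_to_null, null_distribution
from .pairs import (assign_quadrant_labels, exclude_site, find_spouse_pairs,
                    restrict_to_scores, stratify_pairs)
from .pca import (informative_snps, orient_signs, patterson_normalize, run_pca,
                  scree_table, variance_explained_topk)
from .qc import QCParams, run_qc
from .simulate import SimConfig, simulate_cohort
from .stats import spouse_pc_table
from .types import PCResult

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed derived by stable hashing of the stage name.

    Adding a stage never perturbs the streams of existing stages.
    """
    return int(np.random.SeedSequence(
        entropy=(int(master_seed), zlib.crc32(stage.encode()))).generate_state(1)[0])


@dataclass
class PipelineConfig:
    """Validated run configuration; exactly one input mode."""

    out_dir: str
    seed: int = 0
    sim: SimConfig = None
    ped_path: str = None
    map_path: str = None
    fam_path: str = None
    qc: QCParams = field(default_factory=QCParams)
    pca_k: int = 8
    pca_top: int = 30
    anchor_subpop: str = None          # subpop label anchoring PC1/PC2 negative
    exclude_site_label: str = None
    null_replicates: int = 1000
    null_generation: str = "offspring"
    null_pool: str = "quadrant"        # "quadrant" | "subpop"
    pcs: tuple = None                  # 1-based PCs for correlation tables

    def __post_init__(self) -> None:
        simulate_mode = self.sim is not None
        file_mode = self.ped_path is not None
        if simulate_mode == file_mode:
            raise ValueError("provide exactly one of a simulation config or input paths")
        if file_mode and (self.map_path is None or self.fam_path is None):
            raise ValueError("file mode needs ped_path, map_path and fam_path")
        if self.pca_k < 2:
            raise ValueError("pca_k must be >= 2 (quadrant rules need PC1/PC2)")
        if self.null_replicates < 1:
            raise ValueError("null_replicates must be >= 1")
        if self.null_pool not in ("quadrant", "subpop"):
            raise ValueError("null_pool must be 'quadrant' or 'subpop'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("sim", None)
        qc = raw.pop("qc", None)
        cfg = cls(
            sim=SimConfig(**{**sim, "ancestral_freq_range": tuple(
                sim.get("ancestral_freq_range", (0.1, 0.9)))}) if sim else None,
            qc=QCParams(**qc) if qc else QCParams(),
            **raw,
        )
        return cfg

    def canonical(self) -> dict:
        d = {k: v for k, v in asdict(self).items()}
        if self.sim is not None:
            d["sim"] = asdict(self.sim)
        d["qc"] = asdict(self.qc)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the artifact bundle into ``out_dir``.

    Returns a dict of the in-memory results keyed by stage name.  Any stage
    error aborts with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    stage = "config"
    try:
        # ---- input -------------------------------------------------
        stage = "input"
        if config.sim is not None:
            sim_cfg = config.sim
            if sim_cfg.seed == 0 and config.seed != 0:
                sim_cfg = SimConfig(**{**asdict(sim_cfg), "seed": stage_seed(config.seed, "simulate")})
            cohort = simulate_cohort(sim_cfg)
            genotypes, pedigree = cohort.genotypes, cohort.pedigree
            artifacts["cohort"] = cohort
            gio.write_ped_map(genotypes, pedigree, out / "cohort.ped", out / "cohort.map")
            gio.write_fam(pedigree, out / "cohort.fam.tsv")
        else:
            genotypes, _ = gio.read_ped_map(config.ped_path, config.map_path)
            pedigree = gio.read_fam(config.fam_path)
        if genotypes.n_samples == 0 or genotypes.n_snps == 0:
            raise ValueError("empty cohort")

        # ---- QC ----------------------------------------------------
        stage = "qc"
        g_qc, qc_report = run_qc(genotypes, config.qc)
        artifacts["qc_report"] = qc_report
        _write_tsv(pd.DataFrame({"kept_snp_id": qc_report["kept_snp_ids"]}),
                   out / "kept_snps.tsv", "SNPs surviving call-rate, MAF and LD pruning")
        _write_tsv(pd.DataFrame([{k: v for k, v in qc_report.items() if k != "kept_snp_ids"}]),
                   out / "qc_report.tsv", "per-stage SNP counts")

        # ---- PCA ---------------------------------------------------
        stage = "pca"
        g_inf = g_qc.take_snps(informative_snps(g_qc))
        x = patterson_normalize(g_inf)
        pc = run_pca(x, k=config.pca_k, n_eigenvalues=config.pca_top,
                     sample_ids=g_inf.sample_ids)
        anchor_label = config.anchor_subpop
        if anchor_label is None and "subpop" in pedigree.df.columns:
            labels = pedigree.df.loc[pedigree.df["subpop"] != "", "subpop"]
            anchor_label = sorted(labels.unique())[0] if len(labels) else None
        if anchor_label is not None:
            anchor_ids = [i for i, s in zip(pedigree.df["individual_id"], pedigree.df["subpop"])
                          if s == anchor_label and i in set(pc.sample_ids)]
            if anchor_ids:
                pc = orient_signs(pc, anchor_ids, {1: "negative", 2: "negative"})
        artifacts["pc_result"] = pc
        gio.write_scores(pc, out / "scores.tsv")
        _write_tsv(scree_table(pc.eigenvalues), out / "scree.tsv",
                   "eigenvalues of the sample covariance of the normalized genotypes")
        artifacts["variance_within_top"] = variance_explained_topk(
            pc.eigenvalues, min(config.pca_k, len(pc.eigenvalues)),
            min(config.pca_top, len(pc.eigenvalues)))

        # ---- spouse pairs ------------------------------------------
        stage = "pairs"
        pair_set, pair_report = find_spouse_pairs(pedigree, genotypes.sample_ids)
        pair_set = restrict_to_scores(pair_set, pc)
        artifacts["pairs"] = pair_set
        artifacts["pair_report"] = pair_report
        _write_tsv(pair_set.df, out / "pairs.tsv",
                   "spouse pairs identified by in-common children; one row per pair")

        # ---- correlations ------------------------------------------
        stage = "correlate"
        strata = {"all": pair_set, **stratify_pairs(pair_set, by="generation")}
        if config.exclude_site_label:
            for name, sub in list(stratify_pairs(pair_set, by="generation").items()):
                strata[f"{name}-excluding-{config.exclude_site_label}"] = \
                    exclude_site(sub, config.exclude_site_label)
        pcs = list(config.pcs) if config.pcs else None
        corr = spouse_pc_table(strata, pc, pcs=pcs)
        artifacts["correlations"] = corr
        _write_tsv(corr, out / "correlations.tsv",
                   "Pearson r of spouse PC scores with Fisher-z 95% CI and t-test p-value")
        scatter = _scatter_data(pair_set, pc)
        _write_tsv(scatter, out / "pair_scatter.tsv",
                   "per-pair PC1/PC2 scores (male = x, female = y)")

        # ---- null --------------------------------------------------
        stage = "null"
        null_summary, comparison = _null_stage(config, pedigree, pc, corr)
        artifacts["null_summary"] = null_summary
        artifacts["null_comparison"] = comparison
        if null_summary is not None:
            _write_tsv(null_summary.to_frame(), out / "null_summary.tsv",
                       "random within-ethnicity pairing null: per-PC mean and 95% quantile interval")
            _write_tsv(comparison, out / "null_comparison.tsv",
                       "observed spouse correlations vs the random-pairing null")

        # ---- manifest ----------------------------------------------
        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "config": config.canonical(),
            "config_hash": config.config_hash(),
            "master_seed": config.seed,
            "stage_seeds": {s: stage_seed(config.seed, s) for s in ("simulate", "null")},
            "outputs": {},
        }
        for f in sorted(out.iterdir()):
            if f.name != "manifest.json" and f.is_file():
                manifest["outputs"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        artifacts["manifest"] = manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return artifacts


def _scatter_data(pair_set, pc: PCResult) -> pd.DataFrame:
    df = pair_set.df
    mx = pc.scores_for(list(df["male_id"]))
    fy = pc.scores_for(list(df["female_id"]))
    return pd.DataFrame({
        "male_id": df["male_id"], "female_id": df["female_id"],
        "generation": df["generation"],
        "male_pc1": mx[:, 0], "female_pc1": fy[:, 0],
        "male_pc2": mx[:, 1], "female_pc2": fy[:, 1],
    })


def _null_stage(config: PipelineConfig, pedigree, pc: PCResult, corr: pd.DataFrame):
    """Build the candidate pool and run the pairing null for one generation."""
    ped = pedigree.df
    gen = config.null_generation
    members = ped[ped["generation"] == gen] if (ped["generation"] == gen).any() else ped
    members = members[members["individual_id"].isin(set(pc.sample_ids))]
    if config.null_pool == "quadrant":
        labels = assign_quadrant_labels(pc)
        eth = members["individual_id"].map(labels)
        pool = members.assign(ethnicity=eth)
        pool = pool[pool["ethnicity"] != "unassigned"]
    else:
        pool = members.assign(ethnicity=members["subpop"])
        pool = pool[pool["ethnicity"] != ""]
    pool = pool[["individual_id", "sex", "ethnicity"]]
    pcs = sorted(corr["pc"].unique())
    try:
        null_summary = null_distribution(
            pool, pc, pcs=pcs, n_replicates=config.null_replicates,
            seed=stage_seed(config.seed, "null"))
    except ValueError as exc:
        logger.warning("null stage skipped: %s", exc)
        return None, None
    obs_name = gen if (corr["stratum"] == gen).any() else "all"
    observed = corr[corr["stratum"] == obs_name][["pc", "r"]]
    comparison = compare_observed_to_null(observed, null_summary)
    return null_summary, comparison


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def render_summary_table(corr: pd.DataFrame, metadata: dict = None) -> pd.DataFrame:
    """Publication-shaped table: one column per stratum, descriptive rows
    then ``Cor PCk`` rows formatted ``r (ci_low; ci_high)`` at 2 decimals.
    """
    metadata = metadata or {}
    strata = list(dict.fromkeys(corr["stratum"]))
    pcs = sorted(corr["pc"].unique())
    table = {}
    for name in strata:
        sub = corr[corr["stratum"] == name].set_index("pc")
        col = {"N spouse pairs": str(int(sub["n_pairs"].iloc[0]))}
        for key, values in metadata.items():
            col[key] = str(values.get(name, "NA"))
        for pc in pcs:
            if pc in sub.index and np.isfinite(sub.at[pc, "r"]):
                r, lo, hi = sub.at[pc, "r"], sub.at[pc, "ci_low"], sub.at[pc, "ci_high"]
                cell = f"{_round2(r):.2f} ({_round2(lo):.2f}; {_round2(hi):.2f})" \
                    if np.isfinite(lo) else f"{_round2(r):.2f} (NA; NA)"
            else:
                cell = "NA"
            col[f"Cor PC{pc}"] = cell
        table[name] = col
    out = pd.DataFrame(table)
    out.insert(0, "row", out.index)
    return out.reset_index(drop=True)


def _round2(v: float) -> float:
    """Round half away from zero at 2 decimals (report display convention)."""
    import decimal
    return float(decimal.Decimal(repr(float(v))).quantize(decimal.Decimal("0.01"),
                                                   rounding=decimal.ROUND_HALF_UP))


def parse_summary_cell(cell: str) -> tuple[float, float, float]:
    """Inverse of the ``r (lo; hi)`` cell format (2-decimal precision)."""
    r, rest = cell.split(" (")
    lo, hi = rest.rstrip(")").split("; ")
    return float(r), float(lo), float(hi)
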