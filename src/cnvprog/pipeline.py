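"""End-to-end orchestration: simulate/load -> QC -> segment -> analyze.

Stages run in the analysis order preprocess -> segmentation -> instability
-> clustering -> prognosis -> expression integration, writing intermediate
artifacts and a machine-readable report. All randomness derives from the
single configured seed, so a rerun with the same configuration is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .genome import GenomeSpec, hg19_autosomes, generate_probe_map, ProbeMap
from .synthetic_data import (
    CohortConfig, TruthSet, generate_cohort_truth, simulate_l2r_profiles,
    simulate_homozygosity, make_gene_annotation, simulate_expression,
)
from .preprocess import (
    normalize_matrix, compute_dlrs, apply_qc, centralize_profile,
)
from .segmentation import (
    SegConfig, cbs_segment, call_segment_states, build_alteration_matrix, call_cnloh,
)
from .instability import alteration_fractions, summarize_large_events
from .clustering import jaccard_distances, ward_cut, cluster_clinical_association
from .prognosis import (
    burden_association, per_probe_scan, map_genes_to_status, per_gene_scan,
)
from .expression_integration import (
    differential_expression, signal_to_noise_ranking, integrate_cnv_expression,
)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "write_report"]

_STAGES = ["preprocess", "segment", "instability", "cluster", "prognosis", "integrate"]
_DEPS = {
    "segment": "preprocess",
    "instability": "segment",
    "cluster": "instability",
    "prognosis": "instability",
    "integrate": "prognosis",
}


@dataclass
class PipelineConfig:
    """Single configuration for the whole pipeline.

    With ``simulate`` true, inputs are generated by the synthetic-cohort
    module at the configured size; otherwise ``l2r_path``, ``probes_path``
    and ``clinical_path`` must point at existing TSV inputs.
    """

    seed: int = 0
    outdir: str | None = None
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    # input generation / loading
    simulate: bool = True
    n_probes: int = 10_000
    snp_fraction: float = 0.15
    noise_sd: float = 0.15
    purity: float = 1.0
    l2r_path: str | None = None
    probes_path: str | None = None
    clinical_path: str | None = None
    # stage parameters
    dlrs_threshold: float = 0.47
    alpha: float = 1e-6
    gain_threshold: float = 0.25
    loss_threshold: float = -0.25
    min_probes: int = 3
    centralize_min_mb: float = 5.0
    large_event_coverage: float = 0.9
    cluster_k: int = 3
    scan_scopes: list[str] = field(default_factory=lambda: ["lactotroph"])
    run_probe_scan: bool = True
    # expression stage (synthetic only)
    n_genes: int = 2000
    n_de_genes: int = 30
    de_fold_change_range: tuple[float, float] = (2.0, 6.0)
    expression_type: str = "lactotroph"
    cohort: CohortConfig = field(default_factory=CohortConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = raw.pop("cohort", None)
        cfg = cls(**raw)
        if cohort:
            cfg.cohort = CohortConfig(**cohort)
        return cfg

    def validate(self) -> None:
        for s in self.stages:
            if s not in _STAGES:
                raise ValueError(f"unknown stage {s!r}")
            dep = _DEPS.get(s)
            if dep and dep not in self.stages:
                raise ValueError(f"stage {s!r} requires {dep!r} to be enabled")
        if not self.simulate:
            for p in (self.l2r_path, self.probes_path, self.clinical_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"missing input file: {p}")

    def config_hash(self) -> str:
        blob = json.dumps(
            {**{k: v for k, v in asdict(self).items() if k != "cohort"},
             "cohort": repr(self.cohort)},
            sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    metadata: dict
    sections: dict

    def to_dict(self) -> dict:
        return {"metadata": self.metadata, "sections": self.sections}

    @classmethod
    def from_dict(cls, d: dict) -> "ReportBundle":
        return cls(metadata=d.get("metadata", {}), sections=d.get("sections", {}))


def _seed_for(base: int, stage: str) -> int:
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run all enabled stages and return the report bundle.

    Intermediate artifacts are written under ``config.outdir`` when set.
    Any stage failure surfaces with the stage name attached; artifacts
    written before the failure are retained.
    """
    config.validate()
    outdir = Path(config.outdir) if config.outdir else None
    meta = {"config_hash": config.config_hash(), "seed": config.seed,
            "stages": config.stages}
    sections: dict = {}
    genome = hg19_autosomes()

    def save(df: pd.DataFrame, name: str, index: bool = False) -> None:
        if outdir is not None:
            cio.write_tsv(df, outdir / name, index=index,
                          metadata={"config_hash": meta["config_hash"]})

    stage = "inputs"
    try:
        truth: TruthSet | None = None
        if config.simulate:
            probe_map = generate_probe_map(
                genome, config.n_probes, config.snp_fraction,
                seed=_seed_for(config.seed, "probes"))
            truth = generate_cohort_truth(
                config.cohort, probe_map, seed=_seed_for(config.seed, "truth"),
                genome=genome)
            clinical = truth.clinical_table()
            l2r = simulate_l2r_profiles(
                truth, probe_map, noise_sd=config.noise_sd, purity=config.purity,
                seed=_seed_for(config.seed, "l2r"))
            hom = simulate_homozygosity(
                truth, probe_map, config.cohort.baseline_hom_prob,
                seed=_seed_for(config.seed, "hom"))
            if outdir is not None:
                cio.write_probe_map(probe_map, outdir / "probe_map.tsv")
                cio.write_matrix(l2r, outdir / "l2r.tsv")
                cio.write_clinical(clinical, outdir / "clinical.tsv")
                cio.write_truth(truth, outdir / "truth.json")
        else:
            probe_map = cio.read_probe_map(config.probes_path)
            l2r = cio.read_matrix(config.l2r_path)
            clinical = cio.read_clinical(config.clinical_path)
            hom = None

        # ------------------------------------------------------------------
        stage = "preprocess"
        qc_metrics = []
        norm = normalize_matrix(l2r)
        for c in norm.columns:
            qc_metrics.append(compute_dlrs(norm[c].to_numpy(), probe_map, sample_id=str(c)))
        kept, excluded, qc_report = apply_qc(qc_metrics, config.dlrs_threshold)
        save(qc_report, "qc_report.tsv")
        sections["qc"] = {"n_samples": len(norm.columns), "n_excluded": len(excluded),
                          "excluded": excluded}
        norm = norm[kept]
        clinical = clinical.loc[[s for s in kept if s in clinical.index]]
        if "segment" not in config.stages or not kept:
            return ReportBundle(metadata=meta, sections=sections)

        # ------------------------------------------------------------------
        stage = "segment"
        seg_config = SegConfig(
            alpha=config.alpha, gain_threshold=config.gain_threshold,
            loss_threshold=config.loss_threshold, min_probes=config.min_probes,
            seed=_seed_for(config.seed, "cbs"))
        qc_of = {m.sample_id: m for m in qc_metrics}
        seg_parts, offsets = [], {}
        for c in norm.columns:
            v = norm[c].to_numpy()
            segs = cbs_segment(v, probe_map, seg_config, sample_id=str(c))
            # centralization: a pure shift, so boundaries are unchanged and
            # only segment means and the profile need the offset applied
            _, offset = centralize_profile(
                v, segs, min_alteration_mb=config.centralize_min_mb,
                gain_threshold=config.gain_threshold,
                loss_threshold=config.loss_threshold)
            if offset != 0.0:
                segs = segs.assign(mean_l2r=segs["mean_l2r"] + offset)
                norm[c] = v + offset
            offsets[str(c)] = offset
            seg_parts.append(segs)
        segments = call_segment_states(pd.concat(seg_parts, ignore_index=True), seg_config)
        matrix = build_alteration_matrix(segments, probe_map)
        save(segments, "segments.tsv")
        save(matrix, "alteration_matrix.tsv", index=True)
        loh_rows = []
        loh_matrix = pd.DataFrame(
            np.zeros(matrix.shape, dtype=bool), index=matrix.index, columns=matrix.columns)
        if hom is not None and probe_map.is_snp.any():
            snp_global = np.flatnonzero(probe_map.is_snp)
            loh_vals = loh_matrix.to_numpy()
            for ri, c in enumerate(matrix.index):
                intervals, status = call_cnloh(
                    hom[c].to_numpy(), matrix.loc[c].to_numpy(), probe_map, qc_of[str(c)])
                for iv in intervals:
                    loh_rows.append(iv.__dict__)
                    sel = probe_map.probe_indices_in(iv.chrom, iv.start, iv.end)
                    loh_vals[ri, np.intersect1d(sel, snp_global)] = True
            loh_matrix = pd.DataFrame(loh_vals, index=matrix.index,
                                      columns=matrix.columns)
        loh_table = pd.DataFrame(
            loh_rows, columns=["sample_id", "chrom", "start", "end", "n_snps",
                               "mean_homozygosity"])
        save(loh_table, "cnloh.tsv")
        sections["segmentation"] = {
            "n_segments": int(len(segments)),
            "n_altered_segments": int((segments["state"] != "neutral").sum()),
            "centralization_offsets": {k: v for k, v in offsets.items() if v != 0.0},
            "n_cnloh_intervals": int(len(loh_table)),
        }
        if "instability" not in config.stages:
            return ReportBundle(metadata=meta, sections=sections)

        # ------------------------------------------------------------------
        stage = "instability"
        summaries = alteration_fractions(matrix, loh_matrix)
        large = summarize_large_events(matrix, probe_map, genome,
                                       config.large_event_coverage)
        save(summaries, "instability.tsv", index=True)
        save(large, "large_events.tsv")
        per_type = {}
        joined = clinical.join(summaries)
        for t, sub in joined.groupby("tumor_type"):
            per_type[t] = {
                "n": int(len(sub)),
                "median_altered_percent": float(100 * sub["altered_frac"].median()),
                "median_gained_percent": float(100 * sub["gained_frac"].median()),
                "median_deleted_percent": float(100 * sub["deleted_frac"].median()),
                "max_altered_percent": float(100 * sub["altered_frac"].max()),
            }
        sections["instability"] = {
            "per_type": per_type,
            "n_whole_chromosome_events": int((large["scope"] == "chromosome").sum()),
        }

        # ------------------------------------------------------------------
        if "cluster" in config.stages and len(matrix) >= config.cluster_k:
            stage = "cluster"
            dist = jaccard_distances(matrix)
            assignment = ward_cut(dist, k=config.cluster_k)
            save(assignment.labels.to_frame(), "clusters.tsv", index=True)
            assoc = cluster_clinical_association(
                assignment, clinical, seed=_seed_for(config.seed, "fisher"))
            save(assoc, "cluster_associations.tsv")
            med = joined.join(assignment.labels)
            cluster_stats = {
                str(g): {"n": int(len(sub)),
                         "median_altered_percent": float(100 * sub["altered_frac"].median())}
                for g, sub in med.groupby("cluster")
            }
            sections["clustering"] = {"k": config.cluster_k, "clusters": cluster_stats}

        # ------------------------------------------------------------------
        if "prognosis" in config.stages:
            stage = "prognosis"
            n_probes = matrix.shape[1]
            assoc_rows = []
            for scope in ["cohort"] + config.scan_scopes:
                for adjusted in (False, True):
                    try:
                        r = burden_association(summaries, clinical, n_probes,
                                               scope=scope, adjusted=adjusted)
                    except ValueError:
                        continue
                    d = r.as_dict()
                    d.update(scope=scope, adjusted=adjusted)
                    assoc_rows.append(d)
            burden_table = pd.DataFrame(assoc_rows)
            save(burden_table, "burden_associations.tsv")
            headline = [d for d in assoc_rows
                        if d["scope"] == "lactotroph" and d["adjusted"]]
            sections["prognosis"] = {
                "burden_associations": assoc_rows,
                "lactotroph_burden_or": headline[0]["odds_ratio"] if headline else None,
            }
            if config.run_probe_scan:
                for scope in config.scan_scopes:
                    try:
                        scan = per_probe_scan(matrix, clinical, scope=scope,
                                              adjusted=True, adjust_method="BY")
                    except ValueError:
                        continue
                    save(scan.reset_index(names="probe_id"), f"probe_scan_{scope}.tsv")
                    tested = scan["p_value"].notna()
                    sections.setdefault("probe_scans", {})[scope] = {
                        "n_tested": int(tested.sum()),
                        "n_significant_by": int((scan["adjusted_p"] < 0.05).sum()),
                    }

        # ------------------------------------------------------------------
        if "integrate" in config.stages and config.simulate and truth is not None:
            stage = "integrate"
            genes = make_gene_annotation(genome, config.n_genes,
                                         seed=_seed_for(config.seed, "genes"))
            gene_status, _amb = map_genes_to_status(segments, genes,
                                                    samples=list(matrix.index))
            scope = config.expression_type
            try:
                uni = per_gene_scan(gene_status, clinical, scope=scope, adjusted=False)
                multi = per_gene_scan(gene_status, clinical, scope=scope, adjusted=True)
                expr_samples = clinical.index[clinical["tumor_type"] == scope].tolist()
                # recurrence-linked expression effects are planted on genes
                # residing in altered regions (dosage alone, x1.5, cannot
                # clear the 2-fold gate; regulatory amplification can)
                de_rng = np.random.default_rng(_seed_for(config.seed, "de"))
                in_cnv = gene_status.index[(gene_status[expr_samples] != 0).any(axis=1)]
                n_de = min(config.n_de_genes, len(in_cnv))
                lo, hi = config.de_fold_change_range
                de_truth = {}
                for g in de_rng.choice(in_cnv, size=n_de, replace=False):
                    fc = float(np.exp(de_rng.uniform(np.log(lo), np.log(hi))))
                    de_truth[str(g)] = fc if de_rng.random() < 0.7 else 1.0 / fc
                expr = simulate_expression(
                    truth, genes, de_genes=de_truth,
                    seed=_seed_for(config.seed, "expr"),
                    samples=expr_samples)
                groups = clinical.loc[expr.columns, "recurrence"]
                de = differential_expression(expr, groups)
                ranked = signal_to_noise_ranking(expr, groups)
                integration = integrate_cnv_expression(uni, multi, de, genes)
                save(de.reset_index(), "differential_expression.tsv")
                save(integration.reset_index(), "integration.tsv")
                sections["integration"] = {
                    "n_de_planted": n_de,
                    "n_genes_tested": int(uni["p_value"].notna().sum()),
                    "n_significant_univariate": int((uni["adjusted_p"] < 0.05).sum()),
                    "n_significant_multivariate": int((multi["adjusted_p"] < 0.05).sum()),
                    "n_de_genes": int(de["de_flag"].sum()),
                    "n_integrated": int(len(integration)),
                    "top_ranked_gene": str(ranked.index[0]) if len(ranked) else None,
                }
            except ValueError as exc:
                sections["integration"] = {"skipped": str(exc)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return ReportBundle(metadata=meta, sections=sections)


def write_report(bundle: ReportBundle, path, fmt: str = "json") -> None:
    """Persist the report as a single JSON document or a directory of TSVs."""
    path = Path(path)
    if fmt == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(bundle.to_dict(), indent=1, default=str))
    elif fmt == "tsv-dir":
        path.mkdir(parents=True, exist_ok=True)
        (path / "metadata.json").write_text(json.dumps(bundle.metadata, indent=1))
        for name, section in bundle.sections.items():
            pd.json_normalize(section).to_csv(path / f"{name}.tsv", sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
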