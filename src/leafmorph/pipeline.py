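"""End-to-end analysis pipeline.

One call runs: data synthesis (or ingest) -> generalized Procrustes analysis
of the landmarks -> EFD extraction and normalization from the outlines ->
covariance PCA of each trait block with eigenleaf exports -> leave-one-out
LDA of species and of node under each of the three feature sets (landmarks,
EFDs, both) with confusion matrices, feature-set comparison tables and the
node rank correlation -> Spearman trait correlation matrix with hierarchical
clustering.  Every run writes to its own output directory with a verbatim
config copy, a stage log, and a manifest of SHA-256 hashes; identical config
and seed give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import discriminate, io as lio, morphospace, synth, traitcorr
from .efd import EllipticalFourierFeaturizer, reconstruct_contour
from .procrustes import GeneralizedProcrustesAlignment

__all__ = ["RunConfig", "run_pipeline", "PipelineResult"]

logger = logging.getLogger("leafmorph")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    # data source: either a landmark table + outline files, or synthesis
    landmark_table: str | None = None
    table_layout: str = "wide"
    outline_dir: str | None = None
    # synthesis template (used when landmark_table is None)
    n_species: int = 8
    n_classes: int = 4
    separation: float = 3.0
    vines_per_species: int = 3
    nodes_per_vine: int = 10
    noise: float = 1.0
    asymmetry_sd: float = 0.05
    # analysis options
    n_harmonics: int = 20
    n_resample: int = 500
    allow_reflection: bool = True
    eigenleaf_pcs: int = 4
    landmark_sd_multiplier: float = 1.5
    efd_sd_multiplier: float = 1.0
    linkage: str = "complete"
    corr_distance: str = "one_minus_rho"
    # bookkeeping
    seed: int = 0
    output_dir: str = "leafmorph_run"

    def validate(self) -> "RunConfig":
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if self.landmark_table is None:
            if self.n_species < 2:
                raise ValueError("synthesis needs >= 2 species")
            if not 2 <= self.nodes_per_vine <= 30:
                raise ValueError("nodes_per_vine must be within [2, 30]")
        else:
            if not Path(self.landmark_table).exists():
                raise FileNotFoundError(self.landmark_table)
            if self.outline_dir is not None and not Path(self.outline_dir).is_dir():
                raise FileNotFoundError(self.outline_dir)
        return self


@dataclass
class PipelineResult:
    output_dir: Path
    manifest: dict
    summary: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, float_format="%.10g", **kw)


def _load_inputs(cfg: RunConfig):
    if cfg.landmark_table is not None:
        dialect = lio.TableDialect(layout=cfg.table_layout)
        table = lio.read_landmark_table(cfg.landmark_table, dialect)
        outlines = None
        if cfg.outline_dir is not None:
            outlines = []
            for rec in table.records:
                candidates = list(Path(cfg.outline_dir).glob(f"{rec.leaf_id}.*"))
                if not candidates:
                    raise FileNotFoundError(f"no outline/mask for leaf {rec.leaf_id}")
                p = candidates[0]
                if p.suffix.lower() == ".csv":
                    outlines.append(pd.read_csv(p).to_numpy(dtype=float))
                else:
                    from .efd import trace_boundary

                    outlines.append(trace_boundary(lio.load_binary_mask(p)))
        return table, outlines, None
    specs = synth.default_species_specs(
        n_species=cfg.n_species,
        n_classes=cfg.n_classes,
        separation=cfg.separation,
        seed=cfg.seed,
    )
    return synth.synth_dataset(
        specs,
        vines_per_species=cfg.vines_per_species,
        nodes_per_vine=cfg.nodes_per_vine,
        noise=cfg.noise,
        seed=cfg.seed + 1,
        asymmetry_sd=cfg.asymmetry_sd,
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    cfg = config.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: dict = {"seed": cfg.seed}

    try:
        (out / "config.json").write_text(json.dumps(asdict(cfg), indent=2, sort_keys=True))

        stage = "ingest"
        table, outlines, truth = _load_inputs(cfg)
        logger.info("ingest: %d leaves", len(table))
        meta = table.metadata()
        _write_csv(pd.concat([meta, table.coordinate_frame()], axis=1), out / "landmarks_raw.csv")
        if truth is not None:
            _write_csv(truth, out / "ground_truth_params.csv")
        repl = (
            meta.groupby("species")
            .agg(vines=("vine_id", "nunique"), leaves=("vine_id", "size"),
                 max_node=("node_base1", "max"))
        )
        _write_csv(repl, out / "replication_summary.csv")

        stage = "gpa"
        gpa_est = GeneralizedProcrustesAlignment(allow_reflection=cfg.allow_reflection)
        lm_traits = pd.DataFrame(
            gpa_est.fit_transform(table.configurations),
            index=meta.index,
            columns=gpa_est.get_feature_names_out(),
        )
        logger.info("gpa: converged=%s iterations=%d", gpa_est.converged_, gpa_est.n_iter_)
        _write_csv(pd.concat([meta, lm_traits], axis=1), out / "procrustes_landmarks.csv")

        stage = "efd"
        efd_traits = None
        if outlines is not None:
            feat = EllipticalFourierFeaturizer(
                n_harmonics=cfg.n_harmonics, n_resample=cfg.n_resample
            )
            efd_traits = pd.DataFrame(
                feat.fit_transform(outlines),
                index=meta.index,
                columns=feat.get_feature_names_out(),
            )
            nef = lio.NEFFile(
                specimen_ids=list(meta.index),
                harmonics=np.stack(
                    [
                        efd_traits.to_numpy()[i].reshape(4, cfg.n_harmonics).T
                        for i in range(len(efd_traits))
                    ]
                ),
            )
            lio.write_nef(nef, out / "normalized_efd.nef")
            logger.info("efd: %d harmonics x %d leaves", cfg.n_harmonics, len(efd_traits))

        stage = "pca"
        lm_pca = morphospace.fit_pca(lm_traits)
        _write_csv(lm_pca.variance_table(), out / "landmark_pca_variance.csv")
        _write_csv(
            pd.DataFrame(lm_pca.scores_, index=meta.index,
                         columns=[f"PC{i}" for i in range(1, lm_pca.n_components_ + 1)]),
            out / "landmark_pca_scores.csv",
        )
        _write_csv(
            pd.DataFrame(lm_pca.components_, columns=lm_pca.kept_columns_,
                         index=[f"PC{i}" for i in range(1, lm_pca.n_components_ + 1)]),
            out / "landmark_pca_loadings.csv",
        )
        summary["landmark_pca_variance_first4_pct"] = float(
            100.0 * lm_pca.explained_variance_ratio_[: 4].sum()
        )
        eig_rows = []
        for pc in range(1, min(cfg.eigenleaf_pcs, lm_pca.n_components_) + 1):
            for mult in (-cfg.landmark_sd_multiplier, 0.0, cfg.landmark_sd_multiplier):
                shape = morphospace.eigenleaf_landmarks(lm_pca, pc, mult)
                for j, (x, y) in enumerate(shape, start=1):
                    eig_rows.append({"pc": pc, "sd_multiplier": mult, "landmark": j, "x": x, "y": y})
        _write_csv(pd.DataFrame(eig_rows), out / "landmark_eigenleaves.csv", index=False)

        efd_pca = None
        if efd_traits is not None:
            efd_pca = morphospace.fit_pca(efd_traits)
            _write_csv(efd_pca.variance_table(), out / "efd_pca_variance.csv")
            _write_csv(
                pd.DataFrame(efd_pca.scores_, index=meta.index,
                             columns=[f"PC{i}" for i in range(1, efd_pca.n_components_ + 1)]),
                out / "efd_pca_scores.csv",
            )
            summary["efd_pca_variance_first4_pct"] = float(
                100.0 * efd_pca.explained_variance_ratio_[: 4].sum()
            )
            eig_rows = []
            for pc in range(1, min(cfg.eigenleaf_pcs, efd_pca.n_components_) + 1):
                for mult in (-cfg.efd_sd_multiplier, 0.0, cfg.efd_sd_multiplier):
                    cont = morphospace.eigenleaf_contour(efd_pca, pc, mult)
                    for j, (x, y) in enumerate(cont):
                        eig_rows.append({"pc": pc, "sd_multiplier": mult, "i": j, "x": x, "y": y})
            _write_csv(pd.DataFrame(eig_rows), out / "efd_eigenleaves.csv", index=False)
        logger.info("pca: landmark PC1-4 %.1f%%", summary["landmark_pca_variance_first4_pct"])

        stage = "lda"
        species = meta["species"]
        nodes = meta["node_base1"]
        feature_sets = {"landmark": lm_traits}
        if efd_traits is not None:
            feature_sets["efd"] = efd_traits
            feature_sets["both"] = pd.concat([lm_traits, efd_traits], axis=1)
        for name, mat in feature_sets.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res_sp = discriminate.loo_predict(mat, species)
                res_nd = discriminate.loo_predict(mat, nodes)
            cm_sp = discriminate.confusion_matrix(res_sp["actual"], res_sp["predicted"])
            cm_nd = discriminate.confusion_matrix(res_nd["actual"], res_nd["predicted"])
            _write_csv(cm_sp.proportions, out / f"confusion_species_{name}.csv")
            _write_csv(cm_nd.proportions, out / f"confusion_node_{name}.csv")
            summary[f"species_loo_accuracy_{name}_pct"] = 100.0 * cm_sp.accuracy()
            summary[f"node_loo_accuracy_{name}_pct"] = 100.0 * cm_nd.accuracy()
            rho, p = discriminate.node_rank_rho(
                res_nd["actual"].to_numpy(dtype=float),
                res_nd["predicted"].to_numpy(dtype=float),
            )
            summary[f"node_spearman_rho_{name}"] = rho
            summary[f"node_spearman_p_{name}"] = p
            logger.info(
                "lda[%s]: species %.1f%%, node %.1f%%, node rho %.3f",
                name, summary[f"species_loo_accuracy_{name}_pct"],
                summary[f"node_loo_accuracy_{name}_pct"], rho,
            )
        if efd_traits is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cmp_sp = discriminate.feature_set_comparison(lm_traits, efd_traits, species)
                cmp_nd = discriminate.feature_set_comparison(lm_traits, efd_traits, nodes)
            _write_csv(cmp_sp, out / "species_feature_comparison.csv")
            _write_csv(cmp_nd, out / "node_feature_comparison.csv")

        stage = "correlation"
        if efd_traits is not None:
            all_traits = pd.concat([lm_traits, efd_traits], axis=1)
        else:
            all_traits = lm_traits
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corr = traitcorr.spearman_matrix(all_traits)
        _write_csv(corr.rho, out / "trait_spearman_rho.csv")
        _write_csv(corr.p, out / "trait_spearman_p.csv")
        clust = traitcorr.cluster_traits(corr, linkage=cfg.linkage, distance=cfg.corr_distance)
        (out / "trait_clustering.nwk").write_text(clust.newick() + "\n")
        _write_csv(clust.merge_table(), out / "trait_clustering_merges.csv", index=False)
        logger.info("correlation: %d traits clustered (%d constant excluded)",
                    len(clust.trait_names), len(corr.constant_traits))

        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    except Exception as exc:
        partial = sorted(p.name for p in out.iterdir() if p.is_file())
        (out / "manifest.json").write_text(
            json.dumps({"status": "failed", "stage": stage, "files": partial}, indent=2)
        )
        logger.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    logger.removeHandler(handler)
    handler.close()
    manifest = {
        "status": "ok",
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            # config.json records run-local paths; the log records timestamps
            if p.is_file() and p.name not in ("manifest.json", "run.log", "config.json")
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(output_dir=out, manifest=manifest, summary=summary)
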