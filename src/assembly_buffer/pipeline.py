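"""End-to-end orchestration of the synthetic analysis pipeline.

``run_pipeline`` executes the stages in dependency order — synthesize →
structure metrics → variant metrics → enrichment statistics → mechanism
classes → model — writing one TSV/JSON artifact per stage plus a run
manifest recording every seed, the parameter hash, and post-filter record
counts, so inclusion rules can be audited after the fact.  Re-running with
an identical configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import interfaces, model, stats, synthetic, tables, variants
from .errors import ParameterError
from .mechanisms import classify_genes

log = logging.getLogger("assembly_buffer")

ALL_STAGES = ("synthetic", "structure", "variants", "stats", "mechanisms", "model")


@dataclass
class RunConfig:
    """Pipeline configuration; every threshold keeps its standard default."""

    out_dir: str = "results"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    # structure stage
    n_res: int = 100
    interface_center: float = 0.8
    interface_width: float = 0.2
    probe_radius: float = 1.4
    sasa_points: int = 960
    min_interface_area: float = 400.0
    # variant stage
    n_disease: int = 8
    plddt_threshold: float = 50.0
    # stats stage
    class_sizes: dict = field(
        default_factory=lambda: {"AD": 4000, "AR": 4000}
    )
    coassembly_rates: dict = field(
        default_factory=lambda: dict(synthetic.DEFAULT_COASSEMBLY_RATES)
    )
    bootstrap_resamples: int = 10000
    # model stage
    model_n: int = 1000
    model_p: int = 10
    model_beta: tuple[float, ...] = (2.0, -2.0)
    model_missing_rate: float = 0.05
    # optional precomputed inputs (used instead of synthesis when set)
    gene_table_path: str | None = None
    variant_table_path: str | None = None
    corpus_path: str | None = None

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["model_beta"] = list(self.model_beta)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["stages"] = tuple(d.get("stages", ALL_STAGES))
        d["model_beta"] = tuple(d.get("model_beta", (2.0, -2.0)))
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    unknown = [s for s in config.stages if s not in ALL_STAGES]
    if unknown:
        raise ParameterError(f"unknown stages: {unknown}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "stages": list(config.stages),
        "counts": {},
        "outputs": {},
    }
    rng_seed = config.seed

    structure = None
    profile = None
    gene_records = None

    if "synthetic" in config.stages or "structure" in config.stages:
        structure = synthetic.gen_homodimer_structure(
            config.n_res,
            config.interface_center,
            config.interface_width,
            seed=rng_seed,
        )
        from .structures import write_pdb

        pdb_path = out / f"homodimer_{config.config_hash}.pdb"
        write_pdb(structure, pdb_path)
        manifest["outputs"]["structure"] = pdb_path.name
        log.info("synthesized homodimer: %d residues per chain", config.n_res)

    if "structure" in config.stages:
        profile = interfaces.interface_profile(
            structure,
            "A",
            probe_radius=config.probe_radius,
            n_points=config.sasa_points,
            min_area=config.min_interface_area,
        )
        ppath = out / f"interface_profile_{config.config_hash}.tsv"
        tables.write_interface_profile(profile, ppath)
        metrics = {
            "total_area_A2": profile.total_area,
            "passes_min_area": bool(profile.passes_min_area),
            "relative_interface_location": interfaces.relative_interface_location(
                profile
            ),
            "half_area_position": interfaces.half_area_position(profile),
        }
        (out / f"interface_metrics_{config.config_hash}.json").write_text(
            json.dumps(metrics, indent=2, sort_keys=True)
        )
        manifest["outputs"]["interface_profile"] = ppath.name
        manifest["counts"]["interface_residues"] = int(
            len(profile.interface_residues())
        )

    if "variants" in config.stages:
        if config.variant_table_path:
            msets = tables.read_variant_table(config.variant_table_path)
        else:
            mset = synthetic.gen_mutation_positions(
                config.n_res,
                config.n_disease,
                mode="clustered",
                cluster_center=int(config.interface_center * config.n_res),
                spread=max(3, config.n_disease),
                seed=rng_seed + 1,
            )
            msets = {"synthetic": mset}
        if structure is None:
            structure = synthetic.gen_homodimer_structure(
                config.n_res,
                config.interface_center,
                config.interface_width,
                seed=rng_seed,
            )
        rows = []
        for pid, mset in msets.items():
            value = variants.edc(
                structure.chains[0],
                mset.pathogenic_positions,
                plddt_threshold=config.plddt_threshold,
            )
            rows.append({"protein_id": pid, "edc": value})
        edc_path = out / f"edc_{config.config_hash}.tsv"
        pd.DataFrame(rows).to_csv(edc_path, sep="\t", index=False, float_format="%.6g")
        manifest["outputs"]["edc"] = edc_path.name
        manifest["counts"]["variant_sets"] = len(rows)

    if "stats" in config.stages:
        if config.gene_table_path:
            gene_records = tables.read_gene_table(config.gene_table_path)
        else:
            table = synthetic.gen_gene_table(
                config.class_sizes, config.coassembly_rates, seed=rng_seed + 2
            )
            gene_records = table.records
            gpath = out / f"gene_table_{config.config_hash}.tsv"
            tables.write_gene_table(gene_records, gpath)
            manifest["outputs"]["gene_table"] = gpath.name
        result = stats.group_compare(
            gene_records,
            lambda r: r.inheritance == "AD",
            lambda r: r.inheritance == "AR",
        )
        enrich = dataclasses.asdict(result) if result else None
        (out / f"enrichment_{config.config_hash}.json").write_text(
            json.dumps(enrich, indent=2, sort_keys=True)
        )
        manifest["counts"]["genes"] = len(gene_records)
        # bootstrap of a synthetic interface-shift stratum derived from seed
        rng = np.random.default_rng(rng_seed + 3)
        obs = [("DN", x) for x in rng.normal(0.55, 0.1, size=50)]
        boot = stats.bootstrap_shift(
            obs, basemean=0.49, B=config.bootstrap_resamples, seed=rng_seed + 4
        )
        (out / f"bootstrap_{config.config_hash}.json").write_text(
            json.dumps(
                {k: dataclasses.asdict(v) for k, v in boot.items()},
                indent=2,
                sort_keys=True,
            )
        )
        manifest["outputs"]["enrichment"] = f"enrichment_{config.config_hash}.json"

    if "mechanisms" in config.stages:
        if config.corpus_path:
            df = pd.read_csv(config.corpus_path, sep="\t")
            corpus = {
                str(g): grp["text"].tolist() for g, grp in df.groupby("gene_id")
            }
        else:
            corpus = synthetic.gen_mechanism_corpus(
                {"DN": ["GENE_DN1"], "GOF": ["GENE_GOF1"], "LOF": ["GENE_LOF1"]}
            )
        classes = classify_genes(corpus)
        rows = [
            {
                "gene_id": g,
                "mechanism": c.mechanism or "unclassified",
                "evidence": c.evidence[0].sentence if c.evidence else "",
                "source_id": c.evidence[0].source_id if c.evidence else "",
            }
            for g, c in classes.items()
        ]
        mpath = out / f"mechanisms_{config.config_hash}.tsv"
        pd.DataFrame(rows).to_csv(mpath, sep="\t", index=False)
        manifest["outputs"]["mechanisms"] = mpath.name
        manifest["counts"]["classified_genes"] = sum(
            1 for c in classes.values() if c.mechanism
        )

    if "model" in config.stages:
        X, y = synthetic.gen_logistic_features(
            config.model_n,
            config.model_p,
            config.model_beta,
            missing_rate=config.model_missing_rate,
            seed=rng_seed + 5,
        )
        df = pd.DataFrame(X, columns=[f"f{j}" for j in range(config.model_p)])
        prep = model.Preprocessor().fit(df)
        Xp = prep.transform(df)
        fit = model.fit_lasso_cv(
            Xp, y, seed=rng_seed + 6, feature_names=prep.feature_names_
        )
        fit.preprocessor = prep
        scores = model.predict(fit, Xp)["score"].to_numpy()
        fit.t1, fit.t2 = model.derive_thresholds(scores, y.astype(bool))
        (out / f"nonlof_model_{config.config_hash}.json").write_text(fit.to_json())
        manifest["outputs"]["model"] = f"nonlof_model_{config.config_hash}.json"
        manifest["counts"]["model_training_genes"] = int(len(y))

    (out / f"manifest_{config.config_hash}.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest
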