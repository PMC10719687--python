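"""End-to-end orchestration: preprocess -> network fit -> centrality ->
bootstrap stability -> covariate-ladder validation.

A run is driven by a single YAML config; every stage writes its artifact
into the run directory together with a machine-readable manifest (config
hash, fanned-out seeds, package version) so a run is reproducible from the
manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io import (
    read_covariates,
    read_data,
    write_covariates,
    write_data,
    write_edge_list,
    write_graphml,
)
from .mgm import MixedGraphicalModel
from .metrics import centrality_table, extract_bridges
from .preprocess import filter_missingness, log_transform, mask_outliers, residualize
from .stability import bootstrap_network, select_focus_edges
from .synthetic import (
    demo_covariate_model,
    demo_missing_rates,
    demo_model,
    generate_dataset,
    model_to_yaml,
    to_concentration_scale,
)
from .validation import compare_waves, run_covariate_ladder
from .variables import BridgenetError, MixedDataMatrix, SpecificationError

__all__ = ["PipelineConfig", "run_pipeline", "make_demo", "clean_only"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated options for a full pipeline run."""

    data: str
    covariates: str
    output_dir: str
    seed: int = 0
    wave2_data: str | None = None
    wave2_covariates: str | None = None
    k_sd: float = 5.0
    column_threshold: float = 0.025
    adjust_for: tuple[str, ...] = ("sex", "age", "batch")
    penalty: float = 0.0
    rule: str = "wald"
    alpha: float = 0.05
    tau: float | None = None
    correction: str = "bonferroni"
    presence_rule: str = "and"
    ordinal_as_numeric: bool = False
    B: int = 50
    ratio_on_raw: bool = True
    n_validation_pairs: int = 3
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise SpecificationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not Path(self.data).exists():
            raise SpecificationError(f"data path {self.data!r} does not exist")
        if not Path(self.covariates).exists():
            raise SpecificationError(f"covariates path {self.covariates!r} does not exist")
        for p in (self.wave2_data, self.wave2_covariates):
            if p is not None and not Path(p).exists():
                raise SpecificationError(f"path {p!r} does not exist")
        if self.rule not in ("wald", "magnitude"):
            raise SpecificationError(f"unknown presence rule {self.rule!r}")
        if self.rule == "magnitude" and self.tau is None:
            raise SpecificationError("magnitude rule requires tau")
        if not 0 < self.alpha < 1:
            raise SpecificationError("alpha must be in (0, 1)")
        if self.B < 2:
            raise SpecificationError("B must be >= 2")
        self.adjust_for = tuple(self.adjust_for)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["adjust_for"] = list(d["adjust_for"])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def clean_only(data: MixedDataMatrix, k_sd: float = 5.0,
               column_threshold: float = 0.025):
    """Transform + outlier-mask + missingness-filter (no residualisation).

    The un-residualised cleaned matrix is what the bootstrap and the
    validation regressions consume; residualisation happens inside each
    of those stages.
    """
    out = data.copy()
    for j, spec in enumerate(out.specs):
        if spec.is_metabolite:
            col = log_transform(out.values[:, j], spec.name)
            out.values[:, j] = mask_outliers(col, k=k_sd, name=spec.name)
    return filter_missingness(out, column_threshold=column_threshold)


def _stage(run_dir: Path, name: str):
    logger.info("pipeline stage: %s", name)
    (run_dir / "FAILED").write_text(name)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages and return the run directory.

    Re-running with the same config (and inputs) reproduces every
    stochastic output bit-for-bit: the single master seed is fanned out to
    the bootstrap stages through a :class:`numpy.random.SeedSequence`.
    """
    config.validate()
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    seed_boot, seed_aux = (
        int(s) for s in np.random.SeedSequence(config.seed).generate_state(2) % (2**31)
    )
    try:
        _stage(run_dir, "preprocess")
        data = read_data(config.data)
        covariates = read_covariates(config.covariates)
        cleaned, report = clean_only(data, config.k_sd, config.column_threshold)
        kept = np.isin(data.subject_ids, cleaned.subject_ids)
        cov_kept = covariates.select_rows(np.flatnonzero(kept))
        model_input = residualize(cleaned, cov_kept, adjust_for=config.adjust_for)
        write_data(model_input, run_dir / "model_input.tsv")
        (run_dir / "filter_report.txt").write_text(
            f"dropped_columns: {report.dropped_columns}\n"
            f"dropped_rows: {report.dropped_rows}\n"
            f"n_before: {report.n_before}\nn_after: {report.n_after}\n"
            f"row_reduction_pct: {report.row_reduction_pct:.2f}\n"
        )

        _stage(run_dir, "fit")
        model = MixedGraphicalModel(model_input, penalty=config.penalty,
                                    ordinal_as_numeric=config.ordinal_as_numeric)
        res = model.fit(rule=config.rule, alpha=config.alpha, tau=config.tau,
                        correction=config.correction,
                        presence_rule=config.presence_rule)
        write_edge_list(res.network, run_dir / "network_edges.tsv")
        write_graphml(res.network, run_dir / "network.graphml")

        _stage(run_dir, "centrality")
        cent = centrality_table(res.network, ratio_on_raw=config.ratio_on_raw)
        cent.to_csv(run_dir / "centrality.tsv", sep="\t")
        bridges = extract_bridges(res.network)

        _stage(run_dir, "stability")
        summary = bootstrap_network(
            cleaned, B=config.B, seed=seed_boot, covariates=cov_kept,
            adjust_for=config.adjust_for, config=res.config,
        )
        summary.table.to_csv(run_dir / "bootstrap.tsv", sep="\t")
        focus = select_focus_edges(summary, cent)
        focus.to_csv(run_dir / "focus_edges.tsv", sep="\t")

        _stage(run_dir, "validation")
        pairs = _focus_bridge_pairs(focus, model_input, config.n_validation_pairs)
        val_text = "no symptom-metabolite focus pairs found\n"
        consistency = None
        if pairs:
            ladder = run_covariate_ladder(cleaned, cov_kept, pairs, wave="baseline")
            ladder.table.to_csv(run_dir / "validation.tsv", sep="\t", index=False)
            val_text = ladder.table.to_string(index=False) + "\n"
            if config.wave2_data:
                data2 = read_data(config.wave2_data)
                cov2 = read_covariates(config.wave2_covariates)
                cleaned2, _ = clean_only(data2, config.k_sd, config.column_threshold)
                kept2 = np.isin(data2.subject_ids, cleaned2.subject_ids)
                cov2k = cov2.select_rows(np.flatnonzero(kept2))
                ladder2 = run_covariate_ladder(cleaned2, cov2k, pairs, wave="followup")
                ladder2.table.to_csv(run_dir / "validation_wave2.tsv", sep="\t",
                                     index=False)
                comparison = compare_waves(ladder, ladder2)
                comparison.to_csv(run_dir / "wave_comparison.tsv", sep="\t", index=False)
                consistency = comparison.attrs["consistency"]

        if config.make_figures:
            from .plotting import plot_centrality, plot_focus_edges

            plot_centrality(cent, run_dir / "centrality.png")
            plot_focus_edges(focus[focus["presence_fraction"] > 0],
                             run_dir / "focus_edges.png")

        manifest = {
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": config.digest(),
            "seed": config.seed,
            "stage_seeds": {"bootstrap": seed_boot, "aux": seed_aux},
            "n_model_input": model_input.n,
            "n_edges": len(res.network.edges),
            "n_bridges": bridges.n_bridges,
        }
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                          sort_keys=True))
        top3 = cent.index[cent["top3"]].tolist()
        summary_lines = [
            "bridgenet pipeline run",
            f"sample: {report.n_before} -> {model_input.n} subjects "
            f"({report.row_reduction_pct:.1f}% reduction)",
            f"network: {len(res.network.nodes)} nodes, {len(res.network.edges)} edges, "
            f"{bridges.n_bridges} bridge edges",
            f"somatic coverage: {bridges.coverage('somatic'):.1f}%  "
            f"mood/cognition coverage: {bridges.coverage('mood_cognition'):.1f}%",
            f"highly-central nodes: {', '.join(top3)}",
            "",
            "validation:",
            val_text,
        ]
        if consistency is not None:
            summary_lines.insert(5, f"wave consistency: {consistency:.2f}")
        (run_dir / "summary.txt").write_text("\n".join(summary_lines))
    except BridgenetError:
        raise
    else:
        (run_dir / "FAILED").unlink(missing_ok=True)
    return run_dir


def _focus_bridge_pairs(focus, data: MixedDataMatrix, k: int) -> list[tuple[str, str]]:
    pairs = []
    for (a, b), row in focus.iterrows():
        if row["mean_strength"] <= 0:
            continue
        sa, sb = data.spec(a), data.spec(b)
        if sa.is_symptom and sb.is_metabolite:
            pairs.append((a, b))
        elif sb.is_symptom and sa.is_metabolite:
            pairs.append((b, a))
        if len(pairs) >= k:
            break
    return pairs


def make_demo(out_dir: str | Path, seed: int = 0, n: int = 2500,
              waves: int = 2) -> Path:
    """Write the bundled study-shaped synthetic dataset.

    30 ordinal symptom items (4 levels), 46 metabolites, five planted
    bridge couplings, batch/covariate effects and sparse MCAR missingness;
    wave 2 is an independent draw from the same ground truth.  Metabolites
    are written on the raw concentration scale so the cleaning pipeline's
    ln(1+x) transform applies.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = demo_model()
    cov_model = demo_covariate_model()
    (out / "ground_truth.yaml").write_text(model_to_yaml(model))
    wave_seeds = np.random.SeedSequence(seed).generate_state(waves) % (2**31)
    for w in range(waves):
        data, table = generate_dataset(
            model, cov_model, n=n, seed=int(wave_seeds[w]),
            missing_rates=demo_missing_rates(),
        )
        data = to_concentration_scale(data)
        tag = "" if w == 0 else f"_wave{w + 1}"
        write_data(data, out / f"data{tag}.tsv")
        write_covariates(table, out / f"covariates{tag}.tsv")
    (out / "demo_meta.json").write_text(
        json.dumps({"seed": seed, "n": n, "waves": waves, "version": __version__})
    )
    return out
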