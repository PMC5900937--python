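"""End-to-end analysis pipeline: cohort -> itemsets -> rules -> pruning ->
multilevel rules -> latent structure -> report files.

Given a transaction matrix (loaded from CSV or simulated), the pipeline mines
frequent itemsets at the minimum-support threshold, scores and ranks
single-consequent rules, prunes redundant rules per consequent, mines
category-level rules, estimates the tetrachoric/factor/α latent structure,
and writes every table plus a JSON manifest. With a fixed config and seed the
outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .apriori import apriori
from .latent import (
    assign_items,
    cronbach_alpha,
    oblimin_rotate,
    principal_axis_factor,
    tetrachoric_matrix,
)
from .multilevel import category_rule_table, multilevel_rules
from .pruning import prune_all
from .rules import generate_rules, rules_to_frame
from .synthetic import GeneratorConfig, generate, study_default_config
from .transactions import (
    ItemCatalog,
    TransactionMatrix,
    binary_correlation_matrix,
    categorize,
    item_prevalence,
    load_transactions,
    study_catalog,
    venn_counts,
)

__all__ = ["RunConfig", "StageError", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline parameters; thresholds default to the study's 2% / 80%."""

    output_dir: Path
    input_path: Path | None = None  # CSV transaction matrix, or None to simulate
    generator: GeneratorConfig | None = None
    catalog: ItemCatalog | None = None
    min_support: float = 0.02
    min_confidence: float = 0.80
    n_factors: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_support <= 1 or not 0 < self.min_confidence <= 1:
            raise ValueError("thresholds must lie in (0, 1]")
        if self.input_path is not None and self.generator is not None:
            raise ValueError("give either an input path or a generator config")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_csv(df: pd.DataFrame, path: Path, written: list[Path],
               index: bool = False) -> None:
    df.to_csv(path, index=index)
    written.append(path)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to manifest.json)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog = config.catalog or study_catalog()
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "load"
        if config.input_path is not None:
            T = load_transactions(config.input_path, catalog)
        else:
            gen = config.generator or study_default_config(seed=config.seed)
            T = generate(gen)

        stage = "describe"
        prevalence = item_prevalence(T)
        _write_csv(prevalence.rename_axis("item").reset_index(),
                   outdir / "prevalence.csv", written)
        phi = binary_correlation_matrix(T)
        _write_csv(phi, outdir / "phi_correlation.csv", written, index=True)
        venn_tables = {}
        for cat in catalog.categories:
            members = [i for i in catalog.items_in(cat) if i in T.items]
            if 2 <= len(members) <= 4:
                counts = venn_counts(T, members)
                df = pd.DataFrame(
                    [
                        {**{item: bit for item, bit in zip(members, pattern)},
                         "count": count}
                        for pattern, count in sorted(counts.items(), reverse=True)
                    ]
                )
                _write_csv(df, outdir / f"venn_{cat}.csv", written)
                venn_tables[cat] = {"".join(map(str, k)): v for k, v in counts.items()}

        stage = "mine"
        freq = apriori(T, config.min_support)
        freq.to_csv(outdir / "itemsets.csv")
        written.append(outdir / "itemsets.csv")

        stage = "rules"
        scored = generate_rules(freq, config.min_confidence)
        _write_csv(rules_to_frame(scored, display=True),
                   outdir / "rules.csv", written)

        stage = "prune"
        pruned, summary = prune_all(scored)
        _write_csv(rules_to_frame(pruned, display=True),
                   outdir / "pruned_rules.csv", written)

        stage = "multilevel"
        ml = multilevel_rules(T, catalog, config.min_support, config.min_confidence)
        _write_csv(category_rule_table(ml), outdir / "multilevel.csv", written)

        stage = "factors"
        tet = tetrachoric_matrix(T)
        _write_csv(
            pd.DataFrame(tet.values, index=list(T.items), columns=list(T.items)),
            outdir / "tetrachoric.csv", written, index=True,
        )
        paf = principal_axis_factor(tet, config.n_factors)
        rotated = oblimin_rotate(paf, seed=config.seed)
        assignment = assign_items(rotated)
        loading_df = pd.DataFrame(
            rotated.loadings,
            index=list(T.items),
            columns=[f"factor{j + 1}" for j in range(config.n_factors)],
        )
        loading_df["communality"] = rotated.communalities
        loading_df["assigned_factor"] = [
            "" if assignment[i].factor is None else f"factor{assignment[i].factor + 1}"
            for i in T.items
        ]
        _write_csv(loading_df.rename_axis("item"), outdir / "loadings.csv",
                   written, index=True)
        _write_csv(
            pd.DataFrame(
                rotated.factor_correlations,
                index=loading_df.columns[: config.n_factors],
                columns=loading_df.columns[: config.n_factors],
            ),
            outdir / "factor_correlations.csv", written, index=True,
        )

        stage = "alpha"
        alpha_rows = []
        for cat in catalog.categories:
            members = [i for i in catalog.items_in(cat) if i in T.items]
            if len(members) >= 2:
                rep = cronbach_alpha(T, members)
                alpha_rows.append(
                    {"category": cat, "k": rep.k, "alpha": rep.alpha}
                )
        _write_csv(pd.DataFrame(alpha_rows), outdir / "alpha.csv", written)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "n_patients": T.n,
            "n_items": T.m,
            "min_support": config.min_support,
            "min_confidence": config.min_confidence,
            "n_factors": config.n_factors,
            "n_frequent_itemsets": len(freq),
            "n_rules": summary.n_input,
            "n_pruned_rules": summary.n_retained,
            "redundancy_fraction": summary.redundancy_fraction,
            "n_multilevel_rules": len(ml),
            "tetrachoric_smoothed": bool(tet.smoothed),
            "factor_converged": bool(rotated.converged),
            "venn": venn_tables,
            "outputs": sorted(p.name for p in written),
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )
        return manifest
    except Exception as exc:  # clean up partial outputs, then re-raise
        for path in written:
            path.unlink(missing_ok=True)
        (outdir / "manifest.json").unlink(missing_ok=True)
        raise StageError(stage, exc) from exc
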