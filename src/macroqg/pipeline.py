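"""End-to-end orchestration: matrices -> drift tests -> selection -> diet.

A single :class:`RunConfig` drives the whole analysis from input files (or a
simulation request) to tidy delimited output tables plus a machine-readable
run manifest. Statistical non-rejections are results; only data errors abort
a run.
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

from . import __version__
from .ancestral import (AncestralStates, branch_selection_gradients,
                        compare_reconstructions, reconstruct_ml_bm,
                        reconstruct_parsimony, selection_profile)
from .covmat import (CovMatrix, estimate_p_matrix, pool_w_matrices,
                     repeatability, trait_columns, average_replicates)
from .drift import (correlation_test, project_scores, regression_test,
                    size_vector_check)
from .mk import DietStateMap, compare_mk_models, mk_marginal_states
from .simulate import (SimConfig, simulate_diet, simulate_means,
                       simulate_specimens, simulate_tree)
from .tree import Phylogeny, read_newick

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_all", "load_diet_table"]

_METHODS = ("parsimony", "ml", "both")
_CONVENTIONS = ("parent", "child")
ALL_STAGES = ("matrices", "drift", "selection", "diet")


@dataclass
class RunConfig:
    """Flat configuration of a full analysis run."""

    tree_path: str | None = None
    specimen_path: str | None = None
    diet_path: str | None = None
    simulate: bool = False
    factors: tuple[str, ...] = ("sex", "locality")
    min_specimens: int = 35
    min_taxa: int = 5
    alpha: float = 0.05
    alpha_pair: float = 0.01
    extension_tol: float = 1e-4
    method: str = "parsimony"
    w_convention: str = "parent"
    outdir: str = "macroqg_out"
    seed: int = 0
    sim_n_tips: int = 57
    sim_p: int = 35

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")
        if self.w_convention not in _CONVENTIONS:
            raise ValueError(f"w_convention must be one of {_CONVENTIONS}")
        for name in ("min_specimens", "min_taxa", "alpha", "alpha_pair",
                     "extension_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.factors = tuple(self.factors)
        if not self.simulate and not (self.tree_path and self.specimen_path):
            raise ValueError(
                "either set simulate=True or provide tree_path and specimen_path"
            )

    # -- flat key=value round trip ---------------------------------------

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                value = getattr(self, f.name)
                if isinstance(value, tuple):
                    value = ",".join(map(str, value))
                fh.write(f"{f.name} = {'' if value is None else value}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()
        kwargs: dict[str, object] = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            text = raw[f.name]
            if f.name == "factors":
                kwargs[f.name] = tuple(t for t in text.split(",") if t)
            elif f.type in ("int", "sim_n_tips") or isinstance(f.default, bool):
                kwargs[f.name] = text in ("True", "true", "1") \
                    if isinstance(f.default, bool) else int(text)
            elif isinstance(f.default, int) and not isinstance(f.default, bool):
                kwargs[f.name] = int(text)
            elif isinstance(f.default, float):
                kwargs[f.name] = float(text)
            else:
                kwargs[f.name] = text or None
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Outputs of a run: tables in memory plus the paths written."""

    outdir: Path
    tables: dict[str, pd.DataFrame]
    manifest: dict
    tree: Phylogeny


def load_diet_table(path, categories=None) -> DietStateMap:
    frame = pd.read_csv(path)
    if not {"species", "category"} <= set(frame.columns):
        raise ValueError("diet table needs 'species' and 'category' columns")
    cats = categories or tuple(dict.fromkeys(frame["category"]))
    return DietStateMap(categories=cats,
                        states=dict(zip(frame["species"], frame["category"])))


def _species_means(specimens: pd.DataFrame, factors) -> dict[str, np.ndarray]:
    traits = trait_columns(specimens, factors)
    by_specimen = average_replicates(specimens, factors)
    means = by_specimen.groupby("species")[traits].mean()
    return {s: means.loc[s].to_numpy(dtype=float) for s in means.index}


def run_all(config: RunConfig, stages=ALL_STAGES) -> RunReport:
    """Execute the analysis stages in order and write tidy outputs.

    Stages: ``matrices`` (P per species, pooled W per node), ``drift``
    (regression + correlation tests per eligible node), ``selection``
    (ancestral states, per-branch gradients and magnitudes), ``diet``
    (Mk fits and marginal ancestral diets; skipped when no diet data).
    Two runs with the same config produce byte-identical tables.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("macroqg")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)
    tables: dict[str, pd.DataFrame] = {}
    manifest: dict = {
        "package": "macroqg",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "stages": list(stages),
    }

    try:
        # ---- inputs -----------------------------------------------------
        diet: DietStateMap | None = None
        if config.simulate:
            sim = SimConfig(seed=config.seed, n_tips=config.sim_n_tips,
                            p=config.sim_p)
            tree = simulate_tree(sim)
            means_true = simulate_means(tree, sim)
            specimens = simulate_specimens(means_true.tip_means(tree), sim)
            diet = simulate_diet(tree, sim)
            (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
            specimens.to_csv(outdir / "specimens.csv", index=False)
            pd.DataFrame({"species": list(diet.states),
                          "category": list(diet.states.values())}
                         ).to_csv(outdir / "diet.csv", index=False)
        else:
            tree = read_newick(Path(config.tree_path).read_text())
            specimens = pd.read_csv(config.specimen_path)
            if config.diet_path:
                diet = load_diet_table(config.diet_path)

        factors = [f for f in config.factors if f in specimens.columns]
        traits = trait_columns(specimens, factors)
        species_means = _species_means(specimens, factors)
        manifest["n_species"] = tree.n_tips
        manifest["n_traits"] = len(traits)

        # ---- matrices ---------------------------------------------------
        rep = repeatability(specimens, factors)
        tables["repeatability"] = rep.rename_axis("trait").reset_index()
        p_matrices: dict[str, CovMatrix] = {}
        sample_sizes: dict[str, int] = {}
        for species, sub in specimens.groupby("species"):
            sample_sizes[species] = sub["specimen"].nunique()
            p_matrices[species] = estimate_p_matrix(sub, factors, config.alpha)
        w_matrices = pool_w_matrices(tree, p_matrices, sample_sizes,
                                     config.min_specimens)
        tables["sample_sizes"] = pd.DataFrame(
            sorted(sample_sizes.items()), columns=["species", "n_specimens"])

        # ---- drift tests ------------------------------------------------
        if "drift" in stages:
            reg_rows, cor_rows = [], []
            for node in tree.internal_nodes():
                clade = sorted(tree.clade_tips(node))
                if len(clade) < 2:
                    continue
                proj = project_scores({s: species_means[s] for s in clade},
                                      w_matrices[node.label], node=node.label)
                reg = regression_test(tree, node, proj, config.min_taxa,
                                      family_alpha=config.alpha)
                if reg.status == "ok":
                    reg_rows.append({
                        "node": reg.node, "n_taxa": reg.n_taxa,
                        "slope": reg.slope, "ci_low": reg.ci_low,
                        "ci_high": reg.ci_high, "intercept": reg.intercept,
                        "reject_drift": reg.reject_regression,
                    })
                cor = correlation_test(tree, node, proj, config.min_taxa,
                                       config.alpha_pair,
                                       family_alpha=config.alpha)
                if cor.status == "ok":
                    for i, j, r, pval in cor.pairs or []:
                        cor_rows.append({
                            "node": cor.node, "n_taxa": cor.n_taxa,
                            "pc_i": i, "pc_j": j, "correlation": r,
                            "p_value": pval,
                            "reject_drift": cor.reject_correlation,
                        })
                    if not cor.pairs:
                        cor_rows.append({
                            "node": cor.node, "n_taxa": cor.n_taxa,
                            "pc_i": pd.NA, "pc_j": pd.NA,
                            "correlation": np.nan, "p_value": np.nan,
                            "reject_drift": cor.reject_correlation,
                        })
            tables["drift_regression"] = pd.DataFrame(reg_rows)
            tables["drift_correlation"] = pd.DataFrame(cor_rows)
            root_proj = project_scores(species_means,
                                       w_matrices[tree.root.label],
                                       node=tree.root.label)
            r, r2 = size_vector_check(species_means, root_proj)
            manifest["size_pc1_r2"] = r2

        # ---- selection --------------------------------------------------
        if "selection" in stages:
            pars = reconstruct_parsimony(tree, species_means)
            states: AncestralStates = pars
            if config.method in ("ml", "both"):
                ml = reconstruct_ml_bm(tree, species_means)
                if config.method == "ml":
                    states = ml
                else:
                    manifest["reconstruction_correlation"] = \
                        compare_reconstructions(pars, ml)
            grads = branch_selection_gradients(
                tree, states, w_matrices, tol=config.extension_tol,
                convention=config.w_convention)
            profile = selection_profile(tree, grads)
            tables["selection"] = profile
            tables["ancestral_states"] = states.to_frame(traits).reset_index()
            annotations = {child: f"magnitude={est.magnitude:.6g}"
                           for (_, child), est in grads.items()}
            (outdir / "selection_tree.nwk").write_text(
                tree.to_newick(annotations=annotations) + "\n")

        # ---- diet -------------------------------------------------------
        if "diet" in stages and diet is not None:
            fits = compare_mk_models(tree, diet, seed=config.seed)
            tables["diet_models"] = pd.DataFrame(
                [{"model": f.model, "loglik": f.loglik, "k": f.k,
                  "aic": f.aic} for f in fits])
            best = fits[0]
            marg = mk_marginal_states(best, tree, diet)
            rows = []
            for label, probs in marg.probabilities.items():
                rows.append({"node": label, "map_state": marg.argmax(label),
                             **{c: probs[i] for i, c in enumerate(marg.categories)}})
            tables["diet_marginals"] = pd.DataFrame(rows)
            manifest["diet_best_model"] = best.model
            manifest["diet_transitions"] = [list(t) for t in marg.transitions]

        for name, frame in tables.items():
            frame.to_csv(outdir / f"{name}.csv", index=False)
        manifest["tables"] = sorted(tables)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    finally:
        root_logger.removeHandler(handler)
        handler.close()
    return RunReport(outdir=outdir, tables=tables, manifest=manifest, tree=tree)
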