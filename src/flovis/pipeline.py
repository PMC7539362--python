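"""End-to-end orchestration: perception tables, group comparisons, regressions.

The analysis proceeds in four steps, each exposed as a function and as
a CLI subcommand:

1. ``simulate`` — generate a synthetic community (spectra, metadata,
   tree) from a scenario;
2. ``compute`` — build the per-species x per-viewer perception table
   (chromatic contrast in CH units and JND, achromatic contrast in
   Weber units, spectral purity, secondary-peak intensity k);
3. ``compare`` — phylogenetic ANOVA of each metric across pollination
   systems;
4. ``regress`` — PGLS of each metric against SP intensity k with
   ML-estimated Pagel's lambda.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import phylocomp, synthetic, vision
from .features import classify_receptor_class, detect_sp
from .spectra import SpectrumSet, read_spectra, resample, write_spectra
from .vision import ViewingContext, Viewer

__all__ = [
    "assign_pollination_system",
    "compute_perception_table",
    "compare_groups",
    "regress_on_sp",
    "main",
]

log = logging.getLogger("flovis")

#: Share of pollen transfer / fruit set / visitation a visitor group
#: must strictly exceed to count as the main pollinator.
POLLINATOR_SHARE_THRESHOLD = 0.70


def assign_pollination_system(
    shares: dict[str, float], threshold: float = POLLINATOR_SHARE_THRESHOLD
) -> str:
    """Main-pollinator assignment from visitation/efficiency shares.

    The group whose share strictly exceeds the threshold (default 70%)
    is the pollination system; when no group dominates, the species is
    "mixed" (such species are excluded from group comparisons by
    default).
    """
    if not shares:
        raise ValueError("at least one visitation record is required")
    total = sum(shares.values())
    if total > 1.0 + 1e-6:
        raise ValueError(f"shares sum to {total:g} > 1")
    best_group, best_share = max(shares.items(), key=lambda kv: kv[1])
    return best_group if best_share > threshold else "mixed"


#: Which metrics each model family yields. The colour hexagon (and
#: hence purity) is a trichromatic bee construct; RNL chromatic and
#: achromatic contrast apply to every viewer.
_BEE_ONLY = ("chromatic_ch", "purity")


def compute_perception_table(
    spectra: SpectrumSet,
    viewers: list[Viewer],
    ctx: ViewingContext,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Per species x viewer conspicuousness metrics plus SP intensity.

    Columns: ``chromatic_rnl`` (JND, all viewers), ``achromatic``
    (Weber units, all viewers), ``chromatic_ch`` and ``purity``
    (trichromat bee only, NaN otherwise), ``k``, and the metadata
    group labels (pollination system, continent, receptor class).
    """
    missing = [s for s in spectra if s not in metadata.index]
    if missing:
        raise ValueError(f"species missing from metadata: {missing}")

    loci_cache: dict[str, list] = {}
    rows = []
    for species in spectra:
        s = resample(spectra[species])
        sp = detect_sp(s)
        md = metadata.loc[species]
        for viewer in viewers:
            catches = vision.quantum_catch(s, viewer, ctx)
            row = {
                "species": species,
                "viewer": viewer.name,
                "chromatic_rnl": vision.rnl_contrast(catches),
                "achromatic": vision.achromatic_contrast(catches),
                "chromatic_ch": np.nan,
                "purity": np.nan,
                "k": sp.k,
            }
            if viewer.model_family == "trichromat":
                locus = vision.ch_locus(catches)
                if viewer.name not in loci_cache:
                    loci_cache[viewer.name] = vision.spectrum_locus(viewer, ctx)
                row["chromatic_ch"] = vision.ch_distance(locus)
                row["purity"] = vision.purity(locus, loci_cache[viewer.name])
            for col in ("group", "pollination_system", "continent"):
                if col in metadata.columns:
                    row[col] = md[col]
            if "pollination_system" in metadata.columns:
                row["receptor_class"] = classify_receptor_class(md["pollination_system"])
            rows.append(row)
    return pd.DataFrame(rows)


def _metric_columns(viewer_name: str) -> list[str]:
    cols = ["chromatic_rnl", "achromatic"]
    return cols + list(_BEE_ONLY) if viewer_name == "bee" else cols


def compare_groups(
    table: pd.DataFrame,
    tree,
    grouping: str = "group",
    n_sims: int = 1000,
    seed: int | None = None,
    include_mixed: bool = False,
) -> pd.DataFrame:
    """Phylogenetic ANOVA of every metric x viewer across groups.

    Returns one tidy row per metric x viewer with the observed F, the
    simulation p-value and Holm-adjusted pairwise post-hoc p-values.
    Mixed-pollination species are excluded unless ``include_mixed``.
    """
    rng = np.random.default_rng(seed)
    if not include_mixed and grouping in table:
        table = table[table[grouping] != "mixed"]
    out = []
    for viewer_name, sub in table.groupby("viewer", sort=False):
        sub = sub.set_index("species")
        for metric in _metric_columns(viewer_name):
            if metric not in sub or sub[metric].isna().all():
                continue
            traits = pd.DataFrame(
                {"value": sub[metric], "group": sub[grouping]}
            ).dropna()
            res = phylocomp.phyl_anova(
                tree, traits, n_sims=n_sims,
                seed=np.random.default_rng(rng.integers(2**31)),
            )
            pairs = {}
            if res.posthoc_p is not None:
                levels = list(res.posthoc_p.index)
                for i, a in enumerate(levels):
                    for b in levels[i + 1:]:
                        pairs[f"p_{a}_vs_{b}"] = res.posthoc_p.loc[a, b]
            out.append(
                {
                    "viewer": viewer_name,
                    "metric": metric,
                    "grouping": grouping,
                    "F": res.F_obs,
                    "p_phyl": res.p_phyl,
                    "n_sims": res.n_sims,
                    **{f"mean_{g}": m for g, m in res.group_means.items()},
                    **pairs,
                }
            )
    return pd.DataFrame(out)


def regress_on_sp(
    table: pd.DataFrame,
    tree,
    metric: str,
    viewer: str,
) -> phylocomp.PGLSResult:
    """PGLS of one conspicuousness metric against SP intensity k.

    Fits metric ~ 1 + k with the error covariance given by the tree
    under Pagel's-lambda scaling (lambda by ML). The slope sign tells
    whether an SP makes flowers more conspicuous (positive, as for bee
    chromatic contrast and purity) or less (negative, as for avian
    chromatic contrast) to that viewer.
    """
    sub = table[table["viewer"] == viewer].set_index("species")
    data = sub[[metric, "k"]].dropna()
    if data.empty:
        raise ValueError(f"metric {metric!r} unavailable for viewer {viewer!r}")
    return phylocomp.pgls_fit(
        tree, data[metric], X=data[["k"]], lam="ML"
    )


def regress_all(table: pd.DataFrame, tree) -> pd.DataFrame:
    """PGLS of every metric x viewer against k, as one tidy table."""
    rows = []
    for viewer_name in table["viewer"].unique():
        for metric in _metric_columns(viewer_name):
            if metric not in table:
                continue
            try:
                res = regress_on_sp(table, tree, metric, viewer_name)
            except ValueError:
                continue
            rows.append(
                {
                    "viewer": viewer_name,
                    "metric": metric,
                    "slope": res.beta[-1],
                    "intercept": res.beta[0],
                    "lambda_hat": res.lambda_hat,
                    "R2": res.R2,
                    "p_slope": res.p_slope,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CLI

DEFAULT_VIEWER_KINDS = ["bee", "uvs_bird", "vs_bird", "hummingbird"]


def _load_inputs(spectra_path: Path, metadata_path: Path, tree_path: Path):
    spectra = read_spectra(spectra_path, dialect="wide")
    metadata = pd.read_csv(metadata_path, index_col=0)
    tree = phylocomp.read_newick(tree_path)
    return spectra, metadata, tree


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Debug logging to stderr.")
def main(verbose: bool) -> None:
    """Floral colour conspicuousness analysis for pollinator vision."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


@main.command()
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "outdir", type=click.Path(path_type=Path), required=True)
def simulate(seed: int, outdir: Path) -> None:
    """Generate a synthetic community (spectra, metadata, tree)."""
    sc = synthetic.CommunityScenario(seed=seed)
    spectra, meta, tree = synthetic.make_community(sc)
    outdir.mkdir(parents=True, exist_ok=True)
    write_spectra(spectra, outdir / "spectra.csv")
    meta.to_csv(outdir / "metadata.csv")
    phylocomp.write_newick(tree, outdir / "tree.nwk")
    manifest = {
        "seed": seed,
        "n_species": len(spectra),
        "groups": [g.label for g in sc.groups],
        "tree_seed": meta.attrs["tree_seed"],
        "k_seed": meta.attrs["k_seed"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("wrote %d spectra, metadata, tree to %s", len(spectra), outdir)


@main.command()
@click.option("--spectra", "spectra_path", type=click.Path(exists=True, path_type=Path), required=True)
@click.option("--metadata", "metadata_path", type=click.Path(exists=True, path_type=Path), required=True)
@click.option("--tree", "tree_path", type=click.Path(exists=True, path_type=Path), required=True)
@click.option("--out", type=click.Path(path_type=Path), required=True)
def compute(spectra_path: Path, metadata_path: Path, tree_path: Path, out: Path) -> None:
    """Compute the perception table from spectra + metadata."""
    spectra, metadata, _ = _load_inputs(spectra_path, metadata_path, tree_path)
    viewers = [synthetic.make_viewer(k) for k in DEFAULT_VIEWER_KINDS]
    ctx = synthetic.make_context()
    table = compute_perception_table(spectra, viewers, ctx, metadata)
    out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out, index=False)
    log.info("perception table: %d rows -> %s", len(table), out)


@main.command()
@click.option("--table", "table_path", type=click.Path(exists=True, path_type=Path), required=True)
@click.option("--tree", "tree_path", type=click.Path(exists=True, path_type=Path), required=True)
@click.option("--grouping", default="group", show_default=True)
@click.option("--n-sims", type=int, default=1000, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", type=click.Path(path_type=Path), required=True)
def compare(table_path: Path, tree_path: Path, grouping: str, n_sims: int,
            seed: int, out: Path) -> None:
    """Phylogenetic ANOVA of metrics across groups."""
    table = pd.read_csv(table_path)
    tree = phylocomp.read_newick(tree_path)
    res = compare_groups(table, tree, grouping=grouping, n_sims=n_sims, seed=seed)
    out.parent.mkdir(parents=True, exist_ok=True)
    res.to_csv(out, index=False)
    log.info("group comparisons: %d rows -> %s", len(res), out)


@main.command()
@click.option("--table", "table_path", type=click.Path(exists=True, path_type=Path), required=True)
@click.option("--tree", "tree_path", type=click.Path(exists=True, path_type=Path), required=True)
@click.option("--out", type=click.Path(path_type=Path), required=True)
def regress(table_path: Path, tree_path: Path, out: Path) -> None:
    """PGLS of every metric against SP intensity k."""
    table = pd.read_csv(table_path)
    tree = phylocomp.read_newick(tree_path)
    res = regress_all(table, tree)
    out.parent.mkdir(parents=True, exist_ok=True)
    res.to_csv(out, index=False)
    log.info("regressions: %d rows -> %s", len(res), out)


if __name__ == "__main__":
    main()
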