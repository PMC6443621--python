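"""End-to-end analysis pipeline and its run configuration.

One run processes each outline structure (pronotum, elytron)
independently — separate semilandmark counts, separate superimpositions,
separate shape spaces — and writes, per structure: PC scores and
variance fractions, per-subfamily 90% equal-frequency ellipses, pairwise
group distance/p-value tables, disparity tables with the
richness correlation, reconstructed ancestral node shapes with their
length-to-width ratios and nearest-extant-group affinities, and a joint
(extant + node) ordination for phylomorphospace plots.  A JSON manifest
records every parameter and a checksum of every table, so identical
configuration and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from beetlemorph.ancestors import (
    PhyloShapeMap,
    compare_nodes_to_groups,
    length_width_ratio,
    reconstruct_ancestral_shapes,
)
from beetlemorph.discriminate import (
    DEFAULT_SEED,
    distance_matrix_layout,
    pairwise_group_tests,
)
from beetlemorph.disparity import disparity_table, richness_correlation
from beetlemorph.errors import BeetlemorphError, ParameterError
from beetlemorph.ordination import equal_frequency_ellipse, pca
from beetlemorph.procrustes import gpa, project_to_tangent
from beetlemorph.resample import resample_by_arclength
from beetlemorph.simulate import DEFAULT_K, STRUCTURES, generate_study_like_dataset
from beetlemorph.tps_io import (
    SpecimenRecord,
    curves_to_landmarks,
    read_newick,
    read_taxa_table,
    read_tps,
    reconcile_tree_and_table,
    write_tps,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)

CSV_FLOAT_FORMAT = "%.12g"


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    Defaults follow the study design: 25 semilandmarks for the pronotum
    and 50 for the elytron, 10000 permutation rounds, 90% equal-frequency
    ellipses, and equal branch lengths (1.0) for ancestral
    reconstruction.
    """

    out_dir: str = "run"
    tps_paths: dict[str, str] | None = None  # structure -> TPS file
    newick_path: str | None = None
    taxa_path: str | None = None
    simulate: bool = False  # generate the study-like preset instead of reading
    k_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_K))
    rounds: int = 10000
    coverage: float = 0.90
    branch_length: float = 1.0
    gpa_tol: float = 1e-8
    seed: int = DEFAULT_SEED
    node_labels: dict[str, str] = field(default_factory=dict)
    separation: float = 1.0
    cap: int | None = 50
    figures: bool = False

    def validate(self) -> None:
        if self.rounds < 1:
            raise ParameterError(f"rounds must be >= 1, got {self.rounds}")
        if not 0 < self.coverage < 1:
            raise ParameterError(f"coverage must be in (0, 1), got {self.coverage}")
        if self.branch_length <= 0:
            raise ParameterError("branch_length must be positive")
        if not self.simulate:
            for name, p in [
                *(self.tps_paths or {}).items(),
                ("newick", self.newick_path),
                ("taxa", self.taxa_path),
            ]:
                if p is None or not Path(p).exists():
                    raise ParameterError(f"input path for {name!r} missing: {p}")

    def to_manifest_dict(self) -> dict:
        return {
            "k": dict(self.k_map),
            "rounds": self.rounds,
            "coverage": self.coverage,
            "branch_length": self.branch_length,
            "gpa_tol": self.gpa_tol,
            "seed": self.seed,
            "separation": self.separation,
            "cap": self.cap,
            "simulate": self.simulate,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=CSV_FLOAT_FORMAT, lineterminator="\n")


def _prepare_configurations(records: list[SpecimenRecord], k: int):
    """Curve conversion + arc-length resampling -> n x k x 2 stack."""
    configs = np.empty((len(records), k, 2))
    labels = []
    for i, rec in enumerate(records):
        flat = curves_to_landmarks(rec)
        configs[i] = resample_by_arclength(flat.landmarks, k).points
        labels.append(rec.specimen_id)
    return configs, labels


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Halts with the failing stage named on error; outputs written before
    the failure are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        if config.simulate:
            data_dir = out / "data"
            generate_study_like_dataset(
                data_dir,
                seed=config.seed,
                separation=config.separation,
                cap=config.cap,
                k_map=config.k_map,
            )
            tps_paths = {s: data_dir / f"{s}.tps" for s in STRUCTURES}
            newick_path = data_dir / "tree.nwk"
            taxa_path = data_dir / "taxa.csv"
        else:
            tps_paths = {s: Path(p) for s, p in (config.tps_paths or {}).items()}
            newick_path = Path(config.newick_path)
            taxa_path = Path(config.taxa_path)
        taxa = read_taxa_table(taxa_path)
        group_of = taxa.group_of("subfamily")
        ingroup = set(taxa.ingroup_species)
        manifest: dict = {
            "config": config.to_manifest_dict(),
            "inputs": {
                "taxa": _sha256(taxa_path),
                "tree": _sha256(newick_path),
                **{s: _sha256(p) for s, p in tps_paths.items()},
            },
            "structures": {},
            "outputs": {},
        }
        for structure, tps_path in sorted(tps_paths.items()):
            stage = f"{structure}:read"
            records = read_tps(tps_path, structure_tag=structure)
            k = config.k_map[structure]
            stage = f"{structure}:resample"
            configs, labels = _prepare_configurations(records, k)
            groups = np.array([group_of.get(l, "?") for l in labels])
            if (groups == "?").any():
                missing = [l for l, g in zip(labels, groups) if g == "?"]
                raise ParameterError(
                    f"specimens missing from taxa table: {missing[:5]}"
                )
            stage = f"{structure}:align"
            aligned = gpa(configs, tol=config.gpa_tol, labels=labels)
            stage = f"{structure}:ordinate"
            space = pca(aligned.tangent)
            scores = pd.DataFrame(
                {
                    "species_id": labels,
                    "group": groups,
                    "PC1": space.scores[:, 0],
                    "PC2": space.scores[:, 1],
                }
            )
            _write_csv(scores, out / f"{structure}_scores.csv")
            evr = pd.DataFrame(
                {
                    "axis": np.arange(1, len(space.eigenvalues) + 1),
                    "eigenvalue": space.eigenvalues,
                    "variance_fraction": space.variance_fraction,
                }
            )
            _write_csv(evr, out / f"{structure}_eigenvalues.csv")
            ellipse_rows = []
            for g in sorted(set(groups)):
                idx = np.flatnonzero(groups == g)
                if len(idx) < 3 or labels[idx[0]] not in ingroup:
                    continue
                ell = equal_frequency_ellipse(
                    space.scores[idx, :2], coverage=config.coverage
                )
                ellipse_rows.append(
                    {
                        "group": g,
                        "center_x": ell.center[0],
                        "center_y": ell.center[1],
                        "semi_major": ell.semi_axes[0],
                        "semi_minor": ell.semi_axes[1],
                        "orientation_rad": ell.orientation,
                        "coverage": ell.coverage,
                    }
                )
            _write_csv(pd.DataFrame(ellipse_rows), out / f"{structure}_ellipses.csv")
            stage = f"{structure}:compare"
            pairs = pairwise_group_tests(
                aligned.tangent, groups, rounds=config.rounds, seed=config.seed
            )
            _write_csv(pairs, out / f"{structure}_pairwise.csv")
            for metric in ("mahalanobis", "procrustes"):
                M = distance_matrix_layout(pairs, metric)
                _write_csv(M, out / f"{structure}_{metric}_matrix.csv", index=True)
            stage = f"{structure}:disparity"
            subfam_counts = taxa.counts("subfamily")
            ingroup_mask = np.array([l in ingroup for l in labels])
            sub_table = disparity_table(
                aligned.tangent[ingroup_mask],
                groups[ingroup_mask],
                richness=subfam_counts,
            )
            _write_csv(sub_table, out / f"{structure}_disparity_subfamily.csv")
            genus_of = taxa.group_of("genus")
            genus_counts = taxa.counts("genus")
            genera = np.array([genus_of.get(l, "?") for l in labels])
            gen_table = disparity_table(
                aligned.tangent[ingroup_mask],
                genera[ingroup_mask],
                richness=genus_counts,
            )
            # the inclusion rule: genera with more than one described species
            gen_table = gen_table[gen_table["n_species"] > 1].reset_index(drop=True)
            _write_csv(gen_table, out / f"{structure}_disparity_genus.csv")
            if len(gen_table) >= 3:
                try:
                    corr = richness_correlation(gen_table)
                except ParameterError as err:
                    log.info("genus richness correlation skipped: %s", err)
                else:
                    _write_csv(
                        pd.DataFrame(
                            [{"r": corr.r, "p": corr.p, "n_groups": corr.n_groups}]
                        ),
                        out / f"{structure}_richness_correlation.csv",
                    )
            stage = f"{structure}:ancestors"
            tree = read_newick(newick_path)
            reconcile_tree_and_table(tree, taxa, "subfamily")
            tip_means = {}
            for leaf in tree.leaf_node_iter():
                g = leaf.taxon.label
                idx = np.flatnonzero(groups == g)
                if len(idx) == 0:
                    raise ParameterError(f"tree tip {g!r} has no sampled specimens")
                mean_dev = aligned.tangent[idx].mean(axis=0)
                tip_means[g] = (aligned.consensus.ravel() + mean_dev).reshape(
                    aligned.consensus.shape
                )
            shape_map = reconstruct_ancestral_shapes(
                PhyloShapeMap(
                    tree=tree,
                    tip_shapes=tip_means,
                    branch_length=config.branch_length,
                )
            )
            node_shapes = {
                config.node_labels.get(name, name): s
                for name, s in shape_map.node_shapes.items()
            }
            node_records = [
                SpecimenRecord(specimen_id=name, landmarks=shape)
                for name, shape in sorted(node_shapes.items())
            ]
            write_tps(node_records, out / f"{structure}_node_shapes.tps")
            ratios = pd.DataFrame(
                [
                    {"shape": name, "length_width_ratio": length_width_ratio(s)}
                    for name, s in sorted({**tip_means, **node_shapes}.items())
                ]
            )
            _write_csv(ratios, out / f"{structure}_length_width_ratios.csv")
            affinity = compare_nodes_to_groups(
                node_shapes, aligned.tangent, groups, aligned.consensus
            )
            _write_csv(affinity, out / f"{structure}_node_affinity.csv")
            stage = f"{structure}:phylomorphospace"
            node_tangent = np.vstack(
                [
                    project_to_tangent(
                        s.ravel() - aligned.consensus.ravel(), aligned.consensus
                    )[0]
                    for _, s in sorted(node_shapes.items())
                ]
            )
            joint = np.vstack([aligned.tangent, node_tangent])
            joint_space = pca(joint)
            joint_labels = labels + [n for n, _ in sorted(node_shapes.items())]
            joint_kind = ["extant"] * len(labels) + ["node"] * len(node_shapes)
            joint_scores = pd.DataFrame(
                {
                    "label": joint_labels,
                    "kind": joint_kind,
                    "PC1": joint_space.scores[:, 0],
                    "PC2": joint_space.scores[:, 1],
                }
            )
            _write_csv(joint_scores, out / f"{structure}_phylomorphospace_scores.csv")
            manifest["structures"][structure] = {
                "n_specimens": len(records),
                "k": k,
                "gpa_iterations": aligned.iterations,
                "gpa_converged": bool(aligned.converged),
                "pc12_variance_fraction": float(space.variance_fraction[:2].sum()),
            }
            if config.figures:
                stage = f"{structure}:figures"
                _make_figures(out, structure, space, scores, ellipse_rows, sub_table)
        stage = "manifest"
        for p in sorted(out.glob("*.csv")):
            manifest["outputs"][p.name] = _sha256(p)
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    except BeetlemorphError as err:
        raise BeetlemorphError(f"pipeline stage {stage!r} failed: {err}") from err
    return out


def _make_figures(out: Path, structure: str, space, scores: pd.DataFrame, ellipse_rows, sub_table: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from beetlemorph.ordination import FrequencyEllipse

    fig, ax = plt.subplots(figsize=(7, 6))
    for g, sub in scores.groupby("group"):
        ax.scatter(sub["PC1"], sub["PC2"], s=8, label=g, alpha=0.6)
    for row in ellipse_rows:
        ell = FrequencyEllipse(
            center=np.array([row["center_x"], row["center_y"]]),
            semi_axes=np.array([row["semi_major"], row["semi_minor"]]),
            orientation=row["orientation_rad"],
            coverage=row["coverage"],
        )
        b = ell.boundary()
        ax.plot(b[:, 0], b[:, 1], lw=1.2)
    ax.set_xlabel(f"PC1 ({space.variance_fraction[0]:.1%})")
    ax.set_ylabel(f"PC2 ({space.variance_fraction[1]:.1%})")
    ax.legend(fontsize=6, ncol=2)
    fig.savefig(out / f"{structure}_morphospace.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(sub_table["group"], sub_table["procrustes_variance"])
    ax.set_ylabel("Procrustes variance")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(out / f"{structure}_disparity.png", dpi=150)
    plt.close(fig)
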