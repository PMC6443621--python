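"""Synthetic shape-evolution datasets with known ground truth.

The generator emulates the statistical structure a dorsal-outline
morphometric study assumes, without any real specimen data:

* a parametric base outline per structure — a pronotum-like open arc
  with shoulder and anterior-angle controls, and an elongate
  elytron-like arc hitting a requested length-to-greatest-width ratio;
* Brownian motion of group mean shapes along a rooted tree with equal
  branch lengths, acting in the tangent space of the base shape so that
  all simulated variation is shape variation (free of size, position and
  orientation);
* species sampled around their group mean with per-group dispersions
  that are set independently of per-group species richness — the
  disparity/richness decoupling the analysis is designed to detect;
* emitted artifacts (TPS files with semilandmark curves, a Newick tree,
  a CSV taxa table, a JSON truth file) that feed the pipeline end to
  end, with every specimen written under a random similarity transform
  so superimposition has real work to do.

Everything is a deterministic function of the parameters and the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from beetlemorph.errors import ParameterError
from beetlemorph.procrustes import center_and_scale
from beetlemorph.resample import resample_by_arclength
from beetlemorph.ancestors import label_internal_nodes, length_width_ratio
from beetlemorph.tps_io import SpecimenRecord, write_tps

__all__ = [
    "OutlineParams",
    "BmSimulation",
    "SyntheticTruth",
    "make_base_outline",
    "shape_tangent_basis",
    "simulate_bm_on_tree",
    "generate_study_like_dataset",
    "DEFAULT_TREE_NEWICK",
    "DEFAULT_RICHNESS",
    "DEFAULT_VARIANCE_TARGETS",
]

# Topology echoing the study system: a ladder of outgroup families
# subtending a four-subfamily ingroup clade (the "Lucanidae" ancestor is
# the ingroup's stem node).
DEFAULT_TREE_NEWICK = (
    "(Histeridae,(Silphidae,(Trogidae,(Scarabaeidae,(Ochodaeidae,"
    "(Glaresidae,(Passalidae,(Geotrupidae,(Hybosoridae,(Diphyllostomatidae,"
    "((Aesalinae,Syndesinae),(Lampriminae,Lucaninae))))))))))));"
)

INGROUP = ["Aesalinae", "Lampriminae", "Lucaninae", "Syndesinae"]

# Described-species counts for the study system: the ingroup subfamilies
# and ten outgroup families.
DEFAULT_RICHNESS = {
    "Aesalinae": 47,
    "Lampriminae": 11,
    "Lucaninae": 1220,
    "Syndesinae": 25,
    "Diphyllostomatidae": 4,
    "Hybosoridae": 16,
    "Geotrupidae": 16,
    "Passalidae": 11,
    "Glaresidae": 6,
    "Ochodaeidae": 19,
    "Scarabaeidae": 43,
    "Trogidae": 9,
    "Silphidae": 12,
    "Histeridae": 8,
}

# Target per-group Procrustes variances (the planted disparities).  The
# ingroup values follow the study system's subfamily-level table, where
# the small Aesalinae clade is the most disperse and the huge Lucaninae
# clade is not — disparity decoupled from richness by construction.
DEFAULT_VARIANCE_TARGETS = {
    "pronotum": {
        "Aesalinae": 0.0158,
        "Lampriminae": 0.0030,
        "Lucaninae": 0.0111,
        "Syndesinae": 0.0123,
        "_outgroup": 0.0080,
    },
    "elytron": {
        "Aesalinae": 0.0044,
        "Lampriminae": 0.0007,
        "Lucaninae": 0.0025,
        "Syndesinae": 0.0008,
        "_outgroup": 0.0020,
    },
}

STRUCTURES = ("pronotum", "elytron")
DEFAULT_K = {"pronotum": 25, "elytron": 50}


@dataclass
class OutlineParams:
    """Controls for the parametric base outline.

    ratio: length-to-greatest-width ratio along the principal axis.
    shoulder: superellipse exponent (2 = ellipse, larger = squarer
        shoulders, the pronotum's posterior-angle look).
    taper: fore-aft asymmetry in [0, 1); 0 keeps both ends equally wide,
        larger values narrow the apex (the elytron's anterior-angle /
        apex control).
    gap: angular opening (radians) where the closed outline is cut to an
        open arc; the cut sits on the midline so a symmetric parameter
        set yields a symmetric outline.
    """

    ratio: float = 1.571
    shoulder: float = 2.0
    taper: float = 0.0
    gap: float = 0.4


DEFAULT_OUTLINE_PARAMS = {
    "pronotum": OutlineParams(ratio=1.30, shoulder=3.0, taper=0.15, gap=0.5),
    "elytron": OutlineParams(ratio=1.571, shoulder=2.2, taper=0.35, gap=0.35),
}


def make_base_outline(structure: str, k: int | None = None, params: OutlineParams | None = None) -> np.ndarray:
    """Smooth open outline, k points equally spaced by arc length.

    The outline is a tapered superellipse opened at the midline gap,
    densely sampled, resampled by arc length, then rescaled along its
    principal axis until the length-to-greatest-width ratio matches
    ``params.ratio`` to well within 1%.  A symmetric parameter set gives
    an outline exactly symmetric about its midline.
    """
    if structure not in STRUCTURES:
        raise ParameterError(f"unknown structure {structure!r}; expected one of {STRUCTURES}")
    if k is None:
        k = DEFAULT_K[structure]
    if k < 10:
        raise ParameterError(f"base outline needs k >= 10, got {k}")
    p = params if params is not None else DEFAULT_OUTLINE_PARAMS[structure]
    if p.ratio <= 0 or p.shoulder <= 0 or not (0 <= p.taper < 1) or not (0 < p.gap < np.pi):
        raise ParameterError(f"infeasible outline parameters: {p}")
    t = np.linspace(p.gap, 2 * np.pi - p.gap, 4096)
    e = 2.0 / p.shoulder
    x = np.sign(np.cos(t)) * np.abs(np.cos(t)) ** e
    y = np.sign(np.sin(t)) * np.abs(np.sin(t)) ** e
    # taper narrows the end at x = -1 (apex); symmetric in y
    y = y * (1.0 - p.taper * (1.0 - x) / 2.0)
    dense = np.column_stack([x, y])
    pts = resample_by_arclength(dense, k).points
    # iterate the principal-axis rescale; converges in one step for
    # symmetric outlines since the axes then coincide with x/y
    for _ in range(3):
        current = length_width_ratio(pts)
        pts = pts * np.array([p.ratio / current, 1.0])
    normalized, _ = center_and_scale(pts)
    return normalized


def shape_tangent_basis(base: np.ndarray) -> np.ndarray:
    """Orthonormal 2k x 4 basis of the similarity directions at ``base``
    (x/y translation, scaling, rotation); ``base`` must be centered with
    unit centroid size.  BM increments are projected off these columns."""
    k = len(base)
    t1 = np.tile([1.0, 0.0], k) / np.sqrt(k)
    t2 = np.tile([0.0, 1.0], k) / np.sqrt(k)
    s = base.ravel()
    r = np.column_stack([-base[:, 1], base[:, 0]]).ravel()
    r = r / np.linalg.norm(r)
    return np.column_stack([t1, t2, s, r])


def _project_off(basis: np.ndarray, z: np.ndarray) -> np.ndarray:
    return z - basis @ (basis.T @ z)


def smooth_tangent_factor(base: np.ndarray, decay: float = 1.5) -> np.ndarray:
    """Factor F (2k x (2k-4)) for smooth shape perturbations.

    Columns span the shape tangent space at ``base``, ordered from low to
    high spatial frequency along the outline, scaled so that column j
    carries weight ~ (j+1)^-decay (normalized to total 2k-4).  A draw
    ``F @ z`` with z ~ N(0, sigma^2 I) is a smooth deformation —
    neighboring semilandmarks co-vary, as they do in real outlines — with
    expected squared norm (2k-4) * sigma^2, matching an isotropic draw's
    total variance while concentrating it in the low-frequency modes.
    """
    k = len(base)
    t = np.linspace(0.0, np.pi, k)
    cols = []
    f = 0
    while len(cols) < 2 * k:
        for wave in (np.cos(f * t), np.sin(f * t)):
            if np.allclose(wave, 0):
                continue
            for dim in (0, 1):
                col = np.zeros((k, 2))
                col[:, dim] = wave
                cols.append(col.ravel())
        f += 1
    sim = shape_tangent_basis(base)
    # modified Gram-Schmidt against the similarity directions and earlier
    # modes; rank-deficient candidates (e.g. pure translations) drop out
    basis: list[np.ndarray] = []
    for c in cols:
        c = c - sim @ (sim.T @ c)
        for b in basis:
            c = c - (b @ c) * b
        c = c - sim @ (sim.T @ c)
        norm = np.linalg.norm(c)
        if norm > 1e-8:
            basis.append(c / norm)
        if len(basis) == 2 * k - 4:
            break
    Q = np.column_stack(basis)
    m = Q.shape[1]
    w = (np.arange(m) + 1.0) ** -decay
    w *= m / w.sum()
    return Q * np.sqrt(w)


@dataclass
class BmSimulation:
    """Brownian-motion shape evolution on a tree, with full truth."""

    base: np.ndarray  # k x 2, normalized
    rate: float  # per-coordinate variance per unit branch length
    seed: int
    tip_shapes: dict[str, np.ndarray]
    node_shapes: dict[str, np.ndarray]
    tip_deviations: dict[str, np.ndarray]  # flattened tangent rows
    node_deviations: dict[str, np.ndarray]


def simulate_bm_on_tree(tree: dendropy.Tree, base, rate: float, seed: int, branch_length: float = 1.0) -> BmSimulation:
    """Evolve a base shape along a rooted tree by Brownian motion.

    The root carries the base shape.  Each child's tangent deviation is
    its parent's plus a smooth Gaussian increment in the shape tangent
    subspace at the base (orthogonal to translation, rotation and
    scaling; see :func:`smooth_tangent_factor`) with expected squared
    norm ``(2k - 4) * rate * branch_length``.  All true node and tip
    shapes are recorded.
    """
    if rate < 0:
        raise ParameterError(f"rate must be >= 0, got {rate}")
    base = np.asarray(base, dtype=float)
    factor = smooth_tangent_factor(base)
    rng = np.random.default_rng(seed)
    label_internal_nodes(tree)
    k2 = base.size
    node_dev: dict[int, np.ndarray] = {}
    tips: dict[str, np.ndarray] = {}
    nodes: dict[str, np.ndarray] = {}
    sd = np.sqrt(rate * branch_length)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            dev = np.zeros(k2)
        else:
            step = factor @ (rng.normal(0.0, 1.0, factor.shape[1]) * sd)
            dev = node_dev[id(node.parent_node)] + step
        node_dev[id(node)] = dev
        if node.is_leaf():
            tips[node.taxon.label] = dev
        else:
            nodes[node.label] = dev
    return BmSimulation(
        base=base,
        rate=rate,
        seed=seed,
        tip_shapes={k: base + v.reshape(base.shape) for k, v in tips.items()},
        node_shapes={k: base + v.reshape(base.shape) for k, v in nodes.items()},
        tip_deviations=tips,
        node_deviations=nodes,
    )


@dataclass
class SyntheticTruth:
    """Planted ground truth of a generated study-like dataset."""

    seed: int
    tree_newick: str
    bm_rate: float
    separation: float
    richness_map: dict[str, int]
    species: pd.DataFrame  # species_id, group, genus, ingroup, sampled
    base_shapes: dict[str, np.ndarray] = field(default_factory=dict)
    group_means: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    true_node_shapes: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    group_dispersions: dict[str, dict[str, float]] = field(default_factory=dict)
    species_shapes: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def variance_targets(self, structure: str) -> dict[str, float]:
        k2 = self.base_shapes[structure].size
        return {
            g: (k2 - 4) * sd**2 for g, sd in self.group_dispersions[structure].items()
        }


# skewed genus sizes (few large genera, many small), cycled per group —
# emulates the long-tailed richness distribution of real faunas
_GENUS_SIZE_PATTERN = (8, 1, 3, 13, 2, 1, 5, 34, 1, 2, 21, 1, 3, 1, 2)


def _genus_index(i: int) -> int:
    """Genus ordinal (0-based) of the i-th species in a group."""
    g = 0
    acc = 0
    while True:
        acc += _GENUS_SIZE_PATTERN[g % len(_GENUS_SIZE_PATTERN)]
        if i < acc:
            return g
        g += 1


def _species_table(richness_map: dict[str, int]) -> pd.DataFrame:
    rows = []
    for group in sorted(richness_map):
        n = richness_map[group]
        if n < 1:
            raise ParameterError(f"group {group!r} has richness {n} < 1")
        for i in range(n):
            rows.append(
                {
                    "species_id": f"{group}_sp{i + 1:04d}",
                    "genus": f"{group}_g{_genus_index(i) + 1:02d}",
                    "tribe": f"{group}_tribe",
                    "subfamily": group if group in INGROUP else group,
                    "family": "Lucanidae" if group in INGROUP else group,
                    "ingroup": group in INGROUP,
                }
            )
    return pd.DataFrame(rows)


def generate_study_like_dataset(
    out_dir,
    seed: int,
    richness_map: dict[str, int] | None = None,
    dispersion_map: dict[str, dict[str, float]] | None = None,
    separation: float = 1.0,
    bm_rate: float = 1e-4,
    cap: int | None = 50,
    tree_newick: str = DEFAULT_TREE_NEWICK,
    k_map: dict[str, int] | None = None,
    write_files: bool = True,
    structures: tuple[str, ...] = STRUCTURES,
) -> SyntheticTruth:
    """Generate a complete study-like dataset under ``out_dir``.

    Group mean shapes evolve by Brownian motion (per-coordinate variance
    ``bm_rate * separation**2`` per unit branch) on the supplied tree;
    species shapes are drawn isotropically around their group mean with
    per-group dispersions set by ``dispersion_map`` (per-coordinate SD per
    structure), defaulting to SDs that realize the planted per-group
    Procrustes variances of :data:`DEFAULT_VARIANCE_TARGETS` — decoupled
    from richness.  The taxa table enumerates the full richness; shapes
    are generated for the first ``cap`` species of each group (all, when
    ``cap`` is None).

    Emits ``pronotum.tps``, ``elytron.tps`` (one semilandmark curve per
    specimen, random similarity transform applied), ``tree.nwk``,
    ``taxa.csv`` and ``truth.json``; returns the :class:`SyntheticTruth`.

    Everything is a deterministic function of the arguments and ``seed``.
    """
    if separation < 0:
        raise ParameterError(f"separation must be >= 0, got {separation}")
    richness = dict(DEFAULT_RICHNESS if richness_map is None else richness_map)
    k_map = dict(DEFAULT_K if k_map is None else k_map)
    species = _species_table(richness)
    groups = sorted(richness)
    tree = dendropy.Tree.get(data=tree_newick, schema="newick")
    tree.is_rooted = True
    tip_labels = {l.taxon.label for l in tree.leaf_node_iter()}
    if tip_labels != set(groups):
        raise ParameterError(
            f"tree tips {sorted(tip_labels)} do not match richness groups {groups}"
        )
    truth = SyntheticTruth(
        seed=seed,
        tree_newick=tree_newick,
        bm_rate=bm_rate,
        separation=separation,
        richness_map=richness,
        species=species.assign(sampled=False),
    )
    sampled_ids: list[str] = []
    for si, structure in enumerate(structures):
        k = k_map[structure]
        base = make_base_outline(structure, k)
        truth.base_shapes[structure] = base
        # per-group per-coordinate SDs realizing the planted variances
        if dispersion_map is not None and structure in dispersion_map:
            sds = dict(dispersion_map[structure])
        else:
            targets = DEFAULT_VARIANCE_TARGETS[structure]
            sds = {
                g: np.sqrt(targets.get(g, targets["_outgroup"]) / (2 * k - 4))
                for g in groups
            }
        truth.group_dispersions[structure] = sds
        sim = simulate_bm_on_tree(
            tree, base, rate=bm_rate * separation**2, seed=seed * 4 + si
        )
        truth.group_means[structure] = sim.tip_shapes
        truth.true_node_shapes[structure] = sim.node_shapes
        factor = smooth_tangent_factor(base)
        rng = np.random.default_rng((seed * 4 + si) * 1000 + 7)
        records: list[SpecimenRecord] = []
        shapes: dict[str, np.ndarray] = {}
        for group in groups:
            sub = species[species["subfamily"] == group]["species_id"].tolist()
            n_sample = len(sub) if cap is None else min(cap, len(sub))
            for sid in sub[:n_sample]:
                dev = sim.tip_deviations[group] + factor @ rng.normal(
                    0.0, sds[group], factor.shape[1]
                )
                shape = base + dev.reshape(base.shape)
                shapes[sid] = shape
                # random similarity transform: digitized images come at
                # arbitrary position, magnification and slight rotation
                theta = rng.uniform(-0.4, 0.4)
                scale = rng.uniform(80.0, 400.0)
                shift = rng.uniform(100.0, 900.0, 2)
                R = np.array(
                    [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
                )
                records.append(
                    SpecimenRecord(
                        specimen_id=sid,
                        image_ref=f"{sid}.jpg",
                        landmarks=np.empty((0, 2)),
                        curves=[shape @ R.T * scale + shift],
                        structure_tag=structure,
                    )
                )
                if si == 0:
                    sampled_ids.append(sid)
        truth.species_shapes[structure] = shapes
        if write_files:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_tps(records, out / f"{structure}.tps")
    truth.species["sampled"] = truth.species["species_id"].isin(sampled_ids)
    if write_files:
        out = Path(out_dir)
        (out / "tree.nwk").write_text(tree_newick + "\n", encoding="utf-8")
        species.to_csv(out / "taxa.csv", index=False)
        _write_truth_json(out / "truth.json", truth)
    return truth


def _write_truth_json(path, truth: SyntheticTruth) -> None:
    payload = {
        "seed": truth.seed,
        "bm_rate": truth.bm_rate,
        "separation": truth.separation,
        "tree_newick": truth.tree_newick,
        "richness_map": truth.richness_map,
        "group_dispersions": truth.group_dispersions,
        "base_shapes": {s: b.tolist() for s, b in truth.base_shapes.items()},
        "group_means": {
            s: {g: m.tolist() for g, m in d.items()} for s, d in truth.group_means.items()
        },
        "true_node_shapes": {
            s: {n: m.tolist() for n, m in d.items()}
            for s, d in truth.true_node_shapes.items()
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
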