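"""Synthetic wing-landmark datasets and DNA alignments with known truth.

The generator emulates a field study of 19 German mosquito species from
five genera: per-species specimen and sampling-site counts follow the
published sampling table (502 right wings, 18 landmarks each).  Shape
structure is hierarchical — genus-level mean displacements are larger
than species-level ones — with isotropic per-landmark digitization and
biological noise, shared per-site offsets, lognormal centroid-size
variation, and an optional allometric shape-size component.  Raw
configurations are emitted under random rotation, translation and
scaling so that downstream superimposition is fully exercised.

Sequence simulation evolves sites down a branch-length tree under a
reversible nucleotide substitution model, matching the COI validation
arm.  All randomness flows from one seeded generator and the ground
truth (species mean shapes, true sizes, design echo) is returned
alongside every dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .io import LandmarkDataset

#: Default species pool: (abbreviation, genus, n specimens, n sites),
#: mirroring the sampling design of the emulated field study
#: (19 species, 5 genera, 502 specimens, 80 sites overall).
SPECIES_TABLE = (
    ("Ae_ann", "Aedes", 30, 13),
    ("Ae_can", "Aedes", 30, 15),
    ("Ae_cas", "Aedes", 17, 6),
    ("Ae_cin", "Aedes", 30, 11),
    ("Ae_com", "Aedes", 29, 12),
    ("Ae_gen", "Aedes", 24, 13),
    ("Ae_pun", "Aedes", 30, 13),
    ("Ae_ross", "Aedes", 14, 3),
    ("Ae_rust", "Aedes", 29, 12),
    ("Ae_stic", "Aedes", 30, 14),
    ("Ae_vex", "Aedes", 30, 16),
    ("An_clav", "Anopheles", 30, 16),
    ("An_mess", "Anopheles", 19, 13),
    ("An_pb", "Anopheles", 30, 13),
    ("Cq_rich", "Coquillettidia", 30, 11),
    ("Cx_pip", "Culex", 18, 5),
    ("Cx_terr", "Culex", 22, 13),
    ("Cs_ann", "Culiseta", 30, 19),
    ("Cs_mors", "Culiseta", 30, 17),
)


def default_wing_template() -> np.ndarray:
    """Fixed 18-landmark wing-like reference configuration.

    Twelve points trace an elongate wing outline (costa, wing tip,
    posterior margin) and six interior points stand in for vein
    junctions, echoing the standard mosquito wing landmark scheme.
    Unit centroid size; minimum pairwise distance >= 0.02.
    """
    pts = np.array([
        # outline: base -> costa -> tip -> posterior margin -> base
        (0.00, 0.00), (0.55, 0.16), (1.15, 0.26), (1.75, 0.30),
        (2.35, 0.24), (2.80, 0.08), (2.95, -0.12), (2.55, -0.34),
        (2.00, -0.46), (1.40, -0.50), (0.80, -0.44), (0.30, -0.26),
        # interior vein junctions
        (0.90, -0.05), (1.45, 0.02), (2.00, -0.04),
        (1.20, -0.26), (1.80, -0.26), (2.40, -0.20),
    ], dtype=float)
    pts -= pts.mean(axis=0)
    pts /= np.sqrt((pts ** 2).sum())
    return pts


def _generic_template(k: int) -> np.ndarray:
    """Elliptical k-landmark template for non-default landmark counts."""
    theta = 2 * np.pi * np.arange(k) / k
    pts = np.stack([2.0 * np.cos(theta), np.sin(theta)], axis=1)
    pts -= pts.mean(axis=0)
    return pts / np.sqrt((pts ** 2).sum())


@dataclass
class SimulationDesign:
    """Parameters of a synthetic wing-landmark study.

    ``species`` lists (name, genus, n_specimens, n_sites) tuples; the
    default reproduces the emulated study's sampling table.  Landmark
    noise scales are in shape units (fractions of centroid size):
    ``delta`` is the per-landmark species mean displacement scale (the
    genus level uses 2*delta), ``sigma_within`` the within-species
    landmark noise, ``sigma_obs`` the observer digitization noise and
    ``site_sd_factor * sigma_within`` the shared per-site offset scale.
    Centroid sizes are lognormal around evenly log-spaced species
    medians spanning ``size_range`` (largest/smallest); ``beta`` is the
    allometric shape displacement per unit log relative size along a
    species-specific direction.  ``merge_pairs`` makes the second
    species of each pair morphometrically confusable with the first:
    its mean shape is moved to within ``merge_distance * sigma_within``
    (Procrustes distance) of the first's, and it shares the first's
    allometric direction and median size (sibling species of similar
    size and near-identical wings).
    """
    species: tuple = SPECIES_TABLE
    n_per_species: int | None = None        # override table counts
    k: int = 18
    delta: float = 0.04
    sigma_within: float = 0.005
    sigma_obs: float = 0.0035
    site_sd_factor: float = 0.5
    size_median: float = 4.0
    size_range: float = 2.0
    size_cv: float = 0.08
    beta: float = 0.3
    merge_pairs: tuple = ()
    merge_distance: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.k < 4:
            raise ValueError("need k >= 4 landmarks")
        for name, value in (("delta", self.delta),
                            ("sigma_within", self.sigma_within),
                            ("sigma_obs", self.sigma_obs)):
            if value < 0:
                raise ValueError(f"{name} must be >= 0")
        counts = [self.n_per_species or n for _, _, n, _ in self.species]
        if min(counts) < 2:
            raise ValueError("every species needs >= 2 specimens")

    @property
    def species_names(self):
        return [s[0] for s in self.species]

    @property
    def genus_map(self) -> dict:
        return {s[0]: s[1] for s in self.species}


@dataclass
class GroundTruth:
    """True generating quantities recorded next to a synthetic dataset."""
    mean_shapes: dict                     # species -> (k, 2), unit size
    genus_map: dict
    true_sizes: np.ndarray                # per specimen
    allometry_directions: dict            # species -> (2k,) unit vector
    design: SimulationDesign = field(repr=False, default=None)


def simulate_landmark_dataset(design: SimulationDesign,
                              seed: int | None = None):
    """Draw a landmark dataset plus ground truth from a design.

    Returns ``(LandmarkDataset, GroundTruth)``.  ``seed`` overrides
    ``design.seed``; the same seed yields a bit-identical dataset.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    k = design.k
    template = default_wing_template() if k == 18 else _generic_template(k)

    genera = sorted({g for _, g, _, _ in design.species})
    genus_disp = {g: 2 * design.delta * rng.standard_normal((k, 2))
                  for g in genera}
    mean_shapes = {}
    for name, genus, _, _ in design.species:
        m = template + genus_disp[genus] \
            + design.delta * rng.standard_normal((k, 2))
        m -= m.mean(axis=0)
        mean_shapes[name] = m / np.sqrt((m ** 2).sum())
    for a, b in design.merge_pairs:
        direction = rng.standard_normal(2 * k)
        direction /= np.linalg.norm(direction)
        m = mean_shapes[a] + (design.merge_distance * design.sigma_within
                              * direction.reshape(k, 2))
        m -= m.mean(axis=0)
        mean_shapes[b] = m / np.sqrt((m ** 2).sum())

    allom_dirs = {}
    for name, _, _, _ in design.species:
        u = rng.standard_normal(2 * k)
        allom_dirs[name] = u / np.linalg.norm(u)
    for a, b in design.merge_pairs:
        allom_dirs[b] = allom_dirs[a]

    n_species = len(design.species)
    log_range = np.log(design.size_range)
    # evenly log-spaced medians, assigned to species in random order so
    # that size is not collinear with the genus blocks of the table
    log_medians = rng.permutation(
        np.linspace(-log_range / 2, log_range / 2, n_species))
    medians = {s[0]: design.size_median * np.exp(lm)
               for s, lm in zip(design.species, log_medians)}
    for a, b in design.merge_pairs:
        medians[b] = medians[a]
    sigma_log = float(np.sqrt(np.log1p(design.size_cv ** 2)))

    coords, meta_rows, sizes_out = [], [], []
    for name, genus, n_table, n_sites in design.species:
        n = design.n_per_species or n_table
        site_ids = rng.integers(0, n_sites, size=n)
        site_offsets = (design.site_sd_factor * design.sigma_within
                        * rng.standard_normal((n_sites, k, 2)))
        cs = medians[name] * np.exp(sigma_log * rng.standard_normal(n))
        for j in range(n):
            shape = mean_shapes[name] + site_offsets[site_ids[j]] \
                + design.sigma_within * rng.standard_normal((k, 2)) \
                + (design.beta * np.log(cs[j] / design.size_median)
                   * allom_dirs[name].reshape(k, 2))
            shape -= shape.mean(axis=0)
            shape /= np.sqrt((shape ** 2).sum())
            angle = rng.uniform(0, 2 * np.pi)
            c, s = np.cos(angle), np.sin(angle)
            raw = shape @ np.array([[c, s], [-s, c]]) * cs[j]
            raw += rng.uniform(-2, 2, size=2) * design.size_median
            coords.append(raw)
            meta_rows.append({
                "specimen_id": f"{name}_{j + 1:03d}",
                "species": name,
                "genus": genus,
                "site": f"{name}_site{site_ids[j] + 1}",
            })
            sizes_out.append(cs[j])

    dataset = LandmarkDataset(np.stack(coords), pd.DataFrame(meta_rows))
    truth = GroundTruth(mean_shapes, design.genus_map,
                        np.asarray(sizes_out), allom_dirs, design)
    return dataset, truth


def simulate_observer_replicates(dataset: LandmarkDataset,
                                 n_specimens_per_species: int = 3,
                                 n_observers: int = 4,
                                 sigma_obs: float = 0.0035,
                                 seed: int | None = None) -> LandmarkDataset:
    """Replicate digitizations of a specimen subset by several observers.

    For each species, ``n_specimens_per_species`` specimens are chosen
    and re-recorded by ``n_observers`` observers; each replicate is the
    original raw configuration plus isotropic landmark noise of scale
    ``sigma_obs`` (shape units, i.e. scaled by the specimen's centroid
    size).  Replicates keep the original specimen id and carry observer
    ids and a replicate index.
    """
    rng = np.random.default_rng(seed)
    coords, meta_rows = [], []
    for species in pd.unique(dataset.species):
        idx = np.flatnonzero(dataset.species == species)
        if len(idx) < n_specimens_per_species:
            raise ValueError(
                f"species {species} has {len(idx)} specimens, fewer than "
                f"the requested {n_specimens_per_species}")
        chosen = rng.choice(idx, size=n_specimens_per_species, replace=False)
        for i in chosen:
            original = dataset.coords[i]
            centred = original - original.mean(axis=0)
            cs = float(np.sqrt((centred ** 2).sum()))
            for obs in range(1, n_observers + 1):
                noisy = original + (sigma_obs * cs
                                    * rng.standard_normal(original.shape))
                coords.append(noisy)
                row = dataset.meta.iloc[i].to_dict()
                row["observer"] = f"obs{obs}"
                row["replicate"] = str(obs)
                meta_rows.append(row)
    return LandmarkDataset(np.stack(coords), pd.DataFrame(meta_rows))


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def random_binary_tree(labels, rng, edge_range=(0.1, 1.0)) -> dendropy.Tree:
    """Random unrooted binary tree with uniform branch lengths.

    Built by sequential random attachment; the returned dendropy tree
    has a trifurcating seed node (unrooted convention).
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    rng = np.random.default_rng(rng)
    ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = False

    def leaf(lab):
        node = dendropy.Node(taxon=ns.get_taxon(lab))
        node.edge.length = float(rng.uniform(*edge_range))
        return node

    for lab in labels[:3]:
        tree.seed_node.add_child(leaf(lab))
    edges = [c.edge for c in tree.seed_node.child_nodes()]
    for lab in labels[3:]:
        edge = edges[rng.integers(len(edges))]
        old_child = edge.head_node
        parent = edge.tail_node
        split = dendropy.Node()
        parent.remove_child(old_child)
        parent.add_child(split)
        split.add_child(old_child)
        half = old_child.edge.length / 2
        split.edge.length = half
        old_child.edge.length = half
        new_leaf = leaf(lab)
        split.add_child(new_leaf)
        edges += [split.edge, new_leaf.edge, old_child.edge]
        edges.remove(edge)
        edges.append(old_child.edge)
    return tree


def simulate_sequences(tree: dendropy.Tree, model, length: int = 550,
                       seed: int | None = None):
    """Evolve a DNA alignment along ``tree`` under ``model``.

    Root states are drawn from the model's stationary base frequencies
    and propagated along each branch with transition probabilities
    ``P(t) = exp(Q t)``; with Gamma rate variation each site is assigned
    one of the model's discrete rate categories uniformly at random.
    Returns a :class:`~wingmorph.phylo.SequenceAlignment`.
    """
    from .phylo import SequenceAlignment

    rng = np.random.default_rng(seed)
    n_cat = model.n_categories if model.gamma else 1
    rates = model.category_rates() if model.gamma else np.ones(1)
    site_cat = rng.integers(0, n_cat, size=length)
    pi = model.base_freqs
    root = tree.seed_node
    states = {root: rng.choice(4, size=length, p=pi)}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length or 0.0
        parent_states = states[node.parent_node]
        child = np.empty(length, dtype=np.int64)
        for c in range(n_cat):
            mask = site_cat == c
            if not mask.any():
                continue
            P = model.transition_matrix(t * rates[c])
            cum = np.cumsum(P, axis=1)
            u = rng.random(mask.sum())
            child[mask] = (u[:, None]
                           > cum[parent_states[mask]]).sum(axis=1)
        states[node] = child
    labels, rows = [], []
    for leaf_node in tree.leaf_node_iter():
        labels.append(leaf_node.taxon.label)
        rows.append("".join(_BASES[states[leaf_node]]))
    return SequenceAlignment.from_pairs(zip(labels, rows))
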