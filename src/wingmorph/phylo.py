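"""COI likelihood arm: substitution models, pruning, model test, ML search.

Validates morphometric species clusters against a ~550 bp mitochondrial
COI alignment.  Site likelihoods are computed by Felsenstein's pruning
algorithm under reversible nucleotide models (JC69, K80, HKY85), with
among-site rate variation handled by a 4-category discrete Gamma whose
category rates are the means of the distribution's quartile bins.  The
best model is selected by AIC over branch-length-optimized fits on a
fixed neighbor-joining topology; the maximum-likelihood tree search
starts from that NJ tree and alternates per-edge branch-length
optimization with nearest-neighbor-interchange rearrangements.  Column
bootstrap maps bipartition percentages onto the full-data ML tree.

Alignments and trees are small (tens of taxa), so the implementation
favours clarity: site patterns are compressed once, transition matrices
come from a cached symmetric eigendecomposition of the rate matrix, and
per-node scaling guards against underflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import optimize
from scipy.special import gammainc

from .trees import DistanceMatrix, neighbor_joining, _bipartitions

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "-": 4, "N": 4, "?": 4}
_BASES = "ACGT"
#: transitions: A<->G and C<->T
_TRANSITION = np.zeros((4, 4), dtype=bool)
_TRANSITION[0, 2] = _TRANSITION[2, 0] = True
_TRANSITION[1, 3] = _TRANSITION[3, 1] = True


@dataclass
class SequenceAlignment:
    """Fixed-length DNA alignment: labels plus a coded (n, L) matrix.

    Codes 0..3 are A, C, G, T; 4 is gap or fully ambiguous.
    """
    labels: list
    codes: np.ndarray

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate taxon labels")
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.labels):
            raise ValueError("codes must be (n_taxa, length)")

    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_pairs(cls, pairs) -> "SequenceAlignment":
        labels, rows = [], []
        for label, seq in pairs:
            labels.append(label)
            rows.append([_CODE.get(b, 4) for b in seq.upper()])
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        return cls(labels, np.array(rows, dtype=np.uint8))

    @classmethod
    def read_fasta(cls, path) -> "SequenceAlignment":
        records = [(rec.id, str(rec.seq))
                   for rec in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        return cls.from_pairs(records)

    def write_fasta(self, path) -> None:
        bases = np.array(list(_BASES) + ["-"])
        records = [SeqRecord(Seq("".join(bases[row])), id=label,
                             description="")
                   for label, row in zip(self.labels, self.codes)]
        SeqIO.write(records, str(path), "fasta")

    def base_frequencies(self) -> np.ndarray:
        """Empirical A, C, G, T frequencies ignoring gaps/ambiguities."""
        counts = np.array([(self.codes == b).sum() for b in range(4)],
                          dtype=float)
        if counts.sum() == 0:
            raise ValueError("alignment has no unambiguous bases")
        return counts / counts.sum()


def trim_alignment(aln: SequenceAlignment,
                   target_length: int = 550) -> SequenceAlignment:
    """Keep the first ``target_length`` columns (idempotent at length)."""
    if aln.length < target_length:
        raise ValueError(
            f"alignment is {aln.length} bp, shorter than the requested "
            f"{target_length} bp")
    return SequenceAlignment(list(aln.labels),
                             aln.codes[:, :target_length])


# ---------------------------------------------------------------------------
# substitution models
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionModel:
    """Reversible nucleotide model, optionally with discrete Gamma rates.

    ``family`` is JC69 (kappa fixed at 1, equal frequencies), K80
    (kappa free, equal frequencies) or HKY85 (kappa free, unequal
    frequencies).  The rate matrix is normalized to one expected
    substitution per unit branch length.  With ``gamma`` the site rate
    is one of ``n_categories`` equal-probability categories whose rates
    are the within-quartile means of Gamma(alpha, alpha) (mean 1).
    """
    family: str = "HKY85"
    kappa: float = 2.0
    base_freqs: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    gamma: bool = False
    alpha: float = 1.0
    n_categories: int = 4

    def __post_init__(self):
        if self.family not in ("JC69", "K80", "HKY85"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.family == "JC69":
            self.kappa = 1.0
        if self.family in ("JC69", "K80"):
            self.base_freqs = np.full(4, 0.25)
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if self.base_freqs.shape != (4,) or np.any(self.base_freqs <= 0):
            raise ValueError("base_freqs must be 4 positive numbers")
        self.base_freqs = self.base_freqs / self.base_freqs.sum()
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")

    @property
    def n_free_parameters(self) -> int:
        n = 0
        if self.family in ("K80", "HKY85"):
            n += 1                                     # kappa
        if self.family == "HKY85":
            n += 3                                     # empirical frequencies
        if self.gamma:
            n += 1                                     # alpha
        return n

    def rate_matrix(self) -> np.ndarray:
        """Normalized generator Q with stationary ``base_freqs``."""
        pi = self.base_freqs
        Q = np.where(_TRANSITION, self.kappa, 1.0) * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(pi @ np.diag(Q))
        return Q / mu

    def _eigen(self):
        pi = self.base_freqs
        sq = np.sqrt(pi)
        B = self.rate_matrix() * (sq[:, None] / sq[None, :])
        B = (B + B.T) / 2
        lam, V = np.linalg.eigh(B)
        left = V / sq[:, None]            # D^-1/2 V
        right = V.T * sq[None, :]         # V^T D^1/2
        return lam, left, right

    def category_rates(self) -> np.ndarray:
        """Mean rate of each equal-probability Gamma quartile bin."""
        c = self.n_categories
        from scipy.stats import gamma as gamma_dist
        bounds = gamma_dist.ppf(np.linspace(0, 1, c + 1),
                                a=self.alpha, scale=1.0 / self.alpha)
        upper = gammainc(self.alpha + 1, self.alpha * bounds[1:])
        lower = gammainc(self.alpha + 1, self.alpha * bounds[:-1])
        rates = c * (upper - lower)
        return rates / rates.mean()

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t) for one branch length."""
        lam, left, right = self._eigen()
        P = (left * np.exp(lam * t)) @ right
        return np.clip(P, 0.0, None)

    def transition_matrices(self, lengths, rates) -> np.ndarray:
        """P(t * r) for every (length, rate) pair: shape (E, C, 4, 4)."""
        lam, left, right = self._eigen()
        ts = np.asarray(lengths)[:, None] * np.asarray(rates)[None, :]
        expo = np.exp(ts[..., None] * lam)             # (E, C, 4)
        P = np.einsum("il,ecl,lj->ecij", left, expo, right)
        return np.clip(P, 0.0, None)


@dataclass
class ModelFit:
    """A model fitted to an alignment on a tree."""
    model: SubstitutionModel
    tree: dendropy.Tree
    log_likelihood: float
    n_parameters: int

    @property
    def aic(self) -> float:
        return 2 * self.n_parameters - 2 * self.log_likelihood


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------

class _Pruner:
    """Site-pattern-compressed pruning machinery for one tree/alignment."""

    def __init__(self, tree: dendropy.Tree, aln: SequenceAlignment):
        taxa = {lf.taxon.label for lf in tree.leaf_node_iter()}
        if taxa != set(aln.labels):
            raise ValueError(
                "tree taxa and alignment labels differ: "
                f"{sorted(taxa ^ set(aln.labels))}")
        patterns, self.weights = np.unique(aln.codes.T, axis=0,
                                           return_counts=True)
        self.patterns = patterns.T                    # (n_taxa, n_patterns)
        self.row_of = {lab: i for i, lab in enumerate(aln.labels)}
        self.tree = tree
        self.postorder = [nd for nd in tree.postorder_node_iter()]
        self._idx = {nd: i for i, nd in enumerate(self.postorder)}
        self.n_patterns = self.patterns.shape[1]
        # leaf partial templates: (n_patterns, 5 codes -> 4 states)
        eye = np.vstack([np.eye(4), np.ones(4)])
        self._leaf_partial = {
            lab: eye[self.patterns[i]] for lab, i in self.row_of.items()}

    def _edge_lengths(self):
        return np.array([max(nd.edge.length or 0.0, 0.0)
                         for nd in self.postorder[:-1]])

    def _down_partials(self, model):
        """Conditional likelihoods of each subtree, with log scalers."""
        rates = model.category_rates() if model.gamma else np.ones(1)
        lengths = self._edge_lengths()
        P = model.transition_matrices(lengths, rates)   # (E, C, 4, 4)
        down, scaler = {}, {}
        for e, node in enumerate(self.postorder):
            if node.is_leaf():
                part = np.broadcast_to(
                    self._leaf_partial[node.taxon.label],
                    (len(rates), self.n_patterns, 4)).copy()
                sc = np.zeros(self.n_patterns)
            else:
                part = np.ones((len(rates), self.n_patterns, 4))
                sc = np.zeros(self.n_patterns)
                for child in node.child_nodes():
                    ce = self._idx[child]
                    part = part * np.einsum(
                        "cij,cpj->cpi", P[ce], down[child])
                    sc = sc + scaler[child]
                m = part.max(axis=(0, 2))
                m = np.where(m > 0, m, 1.0)
                part = part / m[None, :, None]
                sc = sc + np.log(m)
            down[node], scaler[node] = part, sc
        return down, scaler, P, rates

    def log_likelihood(self, model) -> float:
        down, scaler, _, rates = self._down_partials(model)
        root = self.postorder[-1]
        site = np.einsum("cpi,i->p", down[root],
                         model.base_freqs) / len(rates)
        site = np.clip(site, 1e-300, None)
        return float(self.weights @ (np.log(site) + scaler[root]))

    # -- branch-length optimization ------------------------------------
    def _above_partials(self, model, down, scaler, P, rates):
        """Rest-of-tree partials seen from the parent end of each edge."""
        root = self.postorder[-1]
        above = {root: (np.ones((len(rates), self.n_patterns, 4)),
                        np.zeros(self.n_patterns))}
        for node in self.tree.preorder_node_iter():
            a_part, a_sc = above[node]
            if node is not root:
                # move the parent-side partial across this node's own edge
                a_part = np.einsum("cij,cpj->cpi",
                                   P[self._idx[node]], a_part)
            children = node.child_nodes()
            for child in children:
                part = a_part.copy()
                sc = a_sc.copy()
                for sib in children:
                    if sib is child:
                        continue
                    se = self._idx[sib]
                    part = part * np.einsum("cij,cpj->cpi", P[se], down[sib])
                    sc = sc + scaler[sib]
                m = part.max(axis=(0, 2))
                m = np.where(m > 0, m, 1.0)
                above[child] = (part / m[None, :, None], sc + np.log(m))
        return above

    def optimize_branch_lengths(self, model, sweeps: int = 2,
                                bounds=(1e-8, 10.0), xatol: float = 1e-6):
        """Per-edge bounded scalar optimization, cycling ``sweeps`` times.

        Partials are recomputed between edges, so each accepted update
        is exact; the final log-likelihood is returned.
        """
        lam, left, right = model._eigen()
        rates = model.category_rates() if model.gamma else np.ones(1)
        pi = model.base_freqs
        for _ in range(sweeps):
            for node in list(self.tree.preorder_node_iter()):
                if node is self.postorder[-1]:
                    continue
                down, scaler, P, _ = self._down_partials(model)
                above = self._above_partials(model, down, scaler, P, rates)
                A, _ = above[node]
                D = down[node]
                piA = pi[None, None, :] * A

                def neg(t):
                    expo = np.exp(np.outer(rates, lam) * t)  # (C, 4)
                    Pt = np.einsum("il,cl,lj->cij", left, expo, right)
                    site = np.einsum("cpi,cij,cpj->p", piA, Pt, D) \
                        / len(rates)
                    site = np.clip(site, 1e-300, None)
                    return -float(self.weights @ np.log(site))

                res = optimize.minimize_scalar(
                    neg, bounds=bounds, method="bounded",
                    options={"xatol": xatol, "maxiter": 40})
                # never accept a move that worsens the likelihood
                old = max(node.edge.length or 0.0, bounds[0])
                if res.fun <= neg(old):
                    node.edge.length = float(res.x)
        return self.log_likelihood(model)


def log_likelihood(tree: dendropy.Tree, aln: SequenceAlignment,
                   model: SubstitutionModel) -> float:
    """Pruning log-likelihood of an alignment on a branch-length tree.

    Gaps and Ns are fully ambiguous (partial vector of ones); Gamma
    rate variation averages site likelihoods over the discrete
    categories; per-node scaling prevents underflow.
    """
    return _Pruner(tree, aln).log_likelihood(model)


# ---------------------------------------------------------------------------
# distances and model selection
# ---------------------------------------------------------------------------

def jc_distance_matrix(aln: SequenceAlignment) -> DistanceMatrix:
    """Pairwise Jukes-Cantor corrected distances (gap sites ignored)."""
    n = aln.n_taxa
    D = np.zeros((n, n))
    codes = aln.codes
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] < 4) & (codes[j] < 4)
            total = int(ok.sum())
            if total == 0:
                d = 0.0
            else:
                p = float(((codes[i] != codes[j]) & ok).sum()) / total
                p = min(p, 0.74)        # cap below the JC singularity
                d = -0.75 * np.log1p(-4.0 * p / 3.0)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(list(aln.labels), D)


DEFAULT_CANDIDATES = ("JC69", "JC69+G", "K80", "K80+G", "HKY85", "HKY85+G")


def _make_model(name: str, aln: SequenceAlignment) -> SubstitutionModel:
    family, _, suffix = name.partition("+")
    gamma = suffix == "G"
    freqs = aln.base_frequencies() if family == "HKY85" else np.full(4, 0.25)
    return SubstitutionModel(family=family, kappa=2.0, base_freqs=freqs,
                             gamma=gamma, alpha=0.5)


def _optimize_model(tree, aln, model, rounds: int = 2,
                    sweeps: int = 1) -> ModelFit:
    """Coordinate descent over branch lengths, kappa and alpha."""
    pruner = _Pruner(tree, aln)
    lnl = pruner.log_likelihood(model)
    for _ in range(rounds):
        lnl = pruner.optimize_branch_lengths(model, sweeps=sweeps)
        if model.family in ("K80", "HKY85"):
            def neg_kappa(logk):
                return -pruner.log_likelihood(
                    replace(model, kappa=float(np.exp(logk))))
            res = optimize.minimize_scalar(
                neg_kappa, bounds=np.log([0.05, 100.0]), method="bounded",
                options={"xatol": 1e-3, "maxiter": 30})
            model = replace(model, kappa=float(np.exp(res.x)))
            lnl = -res.fun
        if model.gamma:
            def neg_alpha(loga):
                return -pruner.log_likelihood(
                    replace(model, alpha=float(np.exp(loga))))
            res = optimize.minimize_scalar(
                neg_alpha, bounds=np.log([0.02, 50.0]), method="bounded",
                options={"xatol": 1e-3, "maxiter": 30})
            model = replace(model, alpha=float(np.exp(res.x)))
            lnl = -res.fun
    n_edges = sum(1 for _ in tree.preorder_node_iter()) - 1
    return ModelFit(model, tree, float(lnl),
                    n_edges + model.n_free_parameters)


def model_test(aln: SequenceAlignment, candidates=DEFAULT_CANDIDATES,
               rounds: int = 2):
    """AIC comparison of substitution models on a fixed NJ topology.

    Each candidate's branch lengths (and kappa/alpha where free) are
    optimized on the JC-distance NJ topology; the free parameter count
    is the branch count plus kappa (1), alpha (1) and, for HKY85, the
    three empirical base frequencies.  Returns ``(table, fits)`` where
    the table is sorted by ascending AIC; candidates whose optimization
    fails are flagged and omitted from the fits.
    """
    import pandas as pd

    if aln.n_taxa < 3:
        raise ValueError("model test needs at least 3 taxa")
    base_tree = neighbor_joining(jc_distance_matrix(aln))
    rows, fits = [], {}
    for name in candidates:
        tree = base_tree.clone(depth=1)
        try:
            fit = _optimize_model(tree, aln, _make_model(name, aln),
                                  rounds=rounds)
        except Exception as exc:           # pragma: no cover - defensive
            warnings.warn(f"model {name} failed to optimize: {exc}")
            rows.append({"model": name, "log_likelihood": np.nan,
                         "n_parameters": np.nan, "aic": np.inf})
            continue
        fits[name] = fit
        rows.append({"model": name, "log_likelihood": fit.log_likelihood,
                     "n_parameters": fit.n_parameters, "aic": fit.aic})
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return table, fits


# ---------------------------------------------------------------------------
# ML tree search
# ---------------------------------------------------------------------------

def _internal_edges(tree: dendropy.Tree):
    root = tree.seed_node
    return [nd for nd in tree.preorder_node_iter()
            if nd is not root and not nd.is_leaf()]


def _nni_neighbors(tree: dendropy.Tree):
    """Yield the two NNI rearrangements of every internal edge."""
    n_edges = len(_internal_edges(tree))
    for e_idx in range(n_edges):
        for variant in (0, 1):
            clone = tree.clone(depth=1)
            v = _internal_edges(clone)[e_idx]
            u = v.parent_node
            a, b = v.child_nodes()[:2]
            others = [c for c in u.child_nodes() if c is not v]
            if u is clone.seed_node and len(others) >= 2:
                x, s = a, others[variant]
            else:
                x, s = (a, others[0]) if variant == 0 else (b, others[0])
            u.remove_child(s)
            v.remove_child(x)
            u.add_child(x)
            v.add_child(s)
            yield clone


def ml_search(aln: SequenceAlignment, model: SubstitutionModel,
              start_tree: dendropy.Tree | None = None,
              max_rounds: int = 20, nni_sweeps: int = 1,
              final_sweeps: int = 2) -> ModelFit:
    """NJ-seeded NNI maximum-likelihood tree search.

    Starting from NJ on JC-corrected distances (or ``start_tree``),
    branch lengths are optimized; then all nearest-neighbor-interchange
    neighbors are scored (with a light branch-length sweep each) and
    the best strictly improving move is accepted, until no move
    improves or ``max_rounds`` is reached.  Deterministic.
    """
    if aln.n_taxa < 4:
        raise ValueError("ML search needs at least 4 taxa")
    tree = (start_tree.clone(depth=1) if start_tree is not None
            else neighbor_joining(jc_distance_matrix(aln)))
    best = _Pruner(tree, aln).optimize_branch_lengths(
        model, sweeps=final_sweeps)
    for _ in range(max_rounds):
        best_cand, best_cand_lnl = None, best
        for cand in _nni_neighbors(tree):
            lnl = _Pruner(cand, aln).optimize_branch_lengths(
                model, sweeps=nni_sweeps)
            if lnl > best_cand_lnl + 1e-4:
                best_cand, best_cand_lnl = cand, lnl
        if best_cand is None:
            break
        tree, best = best_cand, best_cand_lnl
    best = _Pruner(tree, aln).optimize_branch_lengths(
        model, sweeps=final_sweeps)
    n_edges = sum(1 for _ in tree.preorder_node_iter()) - 1
    return ModelFit(model, tree, float(best),
                    n_edges + model.n_free_parameters)


def bootstrap_ml(aln: SequenceAlignment, model: SubstitutionModel,
                 n_reps: int = 1000, seed: int | None = None,
                 full_fit: ModelFit | None = None) -> dendropy.Tree:
    """Column-bootstrap supports mapped onto the full-data ML tree.

    Each replicate resamples alignment columns with replacement and
    reruns a reduced-effort search (one NNI round from the full-data ML
    topology); supports are bipartition percentages written to the
    internal node labels of the full tree.  Failed replicates are
    skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    if full_fit is None:
        full_fit = ml_search(aln, model)
    full_tree = full_fit.tree
    target = _bipartitions(full_tree)
    counts = {key: 0 for key in target}
    n_ok = 0
    for _ in range(n_reps):
        cols = rng.integers(0, aln.length, size=aln.length)
        rep = SequenceAlignment(list(aln.labels), aln.codes[:, cols])
        try:
            fit = ml_search(rep, model, start_tree=full_tree,
                            max_rounds=1, nni_sweeps=1, final_sweeps=1)
        except Exception as exc:
            warnings.warn(f"bootstrap replicate failed: {exc}")
            continue
        n_ok += 1
        rep_bip = _bipartitions(fit.tree)
        for key in counts:
            if key in rep_bip:
                counts[key] += 1
    if n_ok == 0:
        raise RuntimeError("all bootstrap replicates failed")
    for key, node in target.items():
        node.label = f"{100.0 * counts[key] / n_ok:g}"
    return full_tree
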