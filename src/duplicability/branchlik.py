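"""Branch-model codon likelihoods and the duplication LRTs.

The log-likelihood of a codon alignment on a multi-leaf gene tree is computed
by Felsenstein's pruning algorithm under the GY94-style model, with a
per-branch-class omega (a background class plus one or more foreground
classes on the post-duplication branches).  Because the model is
time-reversible the likelihood is invariant to root placement.

Two nested-model tests are built on top:

* :func:`asymmetry_test` — do the paralogs of a duplicated species evolve at
  different rates?  Null: background omega0 plus one shared paralog omega1;
  alternative: one omega per paralog; df = (#paralogs - 1).
* :func:`acceleration_test` — did the rate change after duplication?
  Null: a single omega0 on every branch; alternative: omega0 plus one shared
  post-duplication omega1; df = 1.

The module also houses the meta-analytic helpers used when the per-family
tests are considered en masse: Benjamini–Hochberg FDR, Fisher's combined
probability, the chi-square upper tail, and the exact two-sided binomial
split test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import binomtest, chi2
from statsmodels.stats.multitest import multipletests

from . import genetics, gy94
from .codonrates import CodonAlignment
from .treeclass import GeneFamilyTree, split_label


@dataclass
class CodonModelParams:
    kappa: float
    omega_by_class: dict[str, float]
    branch_lengths: dict[frozenset, float]  # keyed by child clade (leaf labels)
    codon_freqs: np.ndarray

    def __post_init__(self):
        if any(w < 0 for w in self.omega_by_class.values()):
            raise ValueError("omegas must be >= 0")
        pi = np.asarray(self.codon_freqs, dtype=float)
        if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("codon_freqs must be non-negative and sum to 1")


@dataclass
class LRTResult:
    lnL_null: float
    lnL_alt: float
    statistic: float
    df: int
    p_raw: float
    p_fdr: float | None = None
    direction: str = "n/a"  # faster | slower | n/a
    omega_null: dict[str, float] = field(default_factory=dict)
    omega_alt: dict[str, float] = field(default_factory=dict)
    family_id: str = ""
    species: str = ""


# ---------------------------------------------------------------------------
# tree/alignment flattening


class _TreeData:
    """Arrays for pruning: postorder edges, leaf patterns, clade keys."""

    def __init__(self, gft: GeneFamilyTree, aln: CodonAlignment):
        tree = gft.tree
        leaves = [lf for lf in tree.leaf_node_iter()]
        labels = [lf.taxon.label for lf in leaves]
        missing = [l for l in labels if split_label(l) not in aln.sequences]
        if missing:
            raise ValueError(f"tree leaves absent from alignment: {missing}")

        nodes = list(tree.postorder_node_iter())
        self.node_index = {id(nd): k for k, nd in enumerate(nodes)}
        self.nodes = nodes
        self.n_nodes = len(nodes)
        self.root_index = self.node_index[id(tree.seed_node)]
        self.children = [[self.node_index[id(c)] for c in nd.child_nodes()]
                         for nd in nodes]
        self.edge_lengths = np.array(
            [float(nd.edge.length or 0.0) for nd in nodes])
        self.clade_keys = []
        for nd in nodes:
            self.clade_keys.append(frozenset(
                lf.taxon.label for lf in nd.leaf_iter()))

        # complete-deletion pattern compression over all tree leaves
        coded = np.stack([genetics.encode_codons(aln.sequences[split_label(l)])
                          for l in labels])
        usable = np.all(coded >= 0, axis=0)
        if not usable.any():
            raise ValueError("no fully ungapped codon columns")
        patterns, counts = np.unique(coded[:, usable], axis=1, return_counts=True)
        self.pattern_counts = counts.astype(float)
        self.leaf_states = {labels[i]: patterns[i] for i in range(len(labels))}
        self.n_patterns = patterns.shape[1]
        self.sequences = [aln.sequences[split_label(l)] for l in labels]

    def edge_class_ids(self, branch_classes, class_order: list[str]) -> np.ndarray:
        """Resolve a {clade-key or label: class} mapping to per-node ids."""
        lookup = {c: k for k, c in enumerate(class_order)}
        ids = np.zeros(self.n_nodes, dtype=int)
        for k, key in enumerate(self.clade_keys):
            label = branch_classes.get(key, "bg") if branch_classes else "bg"
            ids[k] = lookup[label]
        return ids


def _spectra_for(pi: np.ndarray, kappa: float, omegas: np.ndarray,
                 cache: dict | None = None) -> list[gy94.SpectralQ]:
    """Spectral decompositions per omega class, memoised across likelihood
    evaluations that only move branch lengths (the bulk of the optimiser's
    finite-difference calls)."""
    if cache is None:
        return [gy94.spectral(gy94.rate_matrix(kappa, w, pi), pi) for w in omegas]
    out = []
    for w in omegas:
        key = (kappa, float(w))
        if key not in cache:
            if len(cache) > 512:
                cache.clear()
            cache[key] = gy94.spectral(gy94.rate_matrix(kappa, w, pi), pi)
        out.append(cache[key])
    return out


def _pruning_loglik(td: _TreeData, pi: np.ndarray, kappa: float,
                    omegas: np.ndarray, class_ids: np.ndarray,
                    lengths: np.ndarray, cache: dict | None = None) -> float:
    spectra = _spectra_for(pi, kappa, omegas, cache)
    n61 = genetics.N_CODONS
    partials = [None] * td.n_nodes
    log_scale = 0.0
    for k in range(td.n_nodes):
        kids = td.children[k]
        if not kids:
            L = np.zeros((n61, td.n_patterns))
            L[td.leaf_states[td.nodes[k].taxon.label], np.arange(td.n_patterns)] = 1.0
            partials[k] = L
            continue
        L = np.ones((n61, td.n_patterns))
        for c in kids:
            P = spectra[class_ids[c]].transition_matrix(lengths[c])
            L *= P @ partials[c]
            partials[c] = None
        scale = L.max(axis=0)
        scale[scale == 0] = 1.0
        L /= scale
        log_scale += float(td.pattern_counts @ np.log(scale))
        partials[k] = L
    site_lik = pi @ partials[td.root_index]
    return log_scale + float(td.pattern_counts @ np.log(np.maximum(site_lik, 1e-300)))


def codon_loglik(tree: GeneFamilyTree, aln: CodonAlignment,
                 params: CodonModelParams,
                 branch_classes: dict | None = None) -> float:
    """Exact pruning log-likelihood at fixed parameters.

    Branch lengths come from ``params.branch_lengths`` where a clade key is
    present, else from the tree's own edge lengths.
    """
    td = _TreeData(tree, aln)
    class_order = sorted(params.omega_by_class)
    class_ids = td.edge_class_ids(branch_classes or {}, class_order)
    omegas = np.array([params.omega_by_class[c] for c in class_order])
    lengths = td.edge_lengths.copy()
    for k, key in enumerate(td.clade_keys):
        if key in params.branch_lengths:
            lengths[k] = params.branch_lengths[key]
    pi = np.asarray(params.codon_freqs, dtype=float)
    return _pruning_loglik(td, pi, params.kappa, omegas, class_ids, lengths)


# ---------------------------------------------------------------------------
# maximum-likelihood fitting


_LOG_T_BOUNDS = (math.log(1e-6), math.log(5.0))
_LOG_K_BOUNDS = (math.log(0.05), math.log(50.0))
_LOG_W_BOUNDS = (math.log(1e-4), math.log(60.0))


def _fit(td: _TreeData, pi: np.ndarray, class_ids: np.ndarray, n_classes: int,
         x0: np.ndarray | None = None):
    """Joint bounded quasi-Newton ML over (log branch lengths, log kappa,
    log omegas).  The edge above the root is unidentifiable and held at 0."""
    free = [k for k in range(td.n_nodes) if k != td.root_index]
    n_edges = len(free)
    cache: dict = {}

    def unpack(x):
        lengths = np.zeros(td.n_nodes)
        lengths[free] = np.exp(x[:n_edges])
        kappa = math.exp(x[n_edges])
        omegas = np.exp(x[n_edges + 1:])
        return lengths, kappa, omegas

    def nll(x):
        lengths, kappa, omegas = unpack(x)
        return -_pruning_loglik(td, pi, kappa, omegas, class_ids, lengths,
                                cache=cache)

    if x0 is None:
        t_init = np.clip(td.edge_lengths[free], 5e-4, 4.0)
        x0 = np.concatenate([np.log(t_init), [math.log(2.0)],
                             np.full(n_classes, math.log(0.3))])
    bounds = ([_LOG_T_BOUNDS] * n_edges + [_LOG_K_BOUNDS]
              + [_LOG_W_BOUNDS] * n_classes)
    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                   options=dict(maxiter=1000, ftol=1e-12))
    lengths, kappa, omegas = unpack(res.x)
    return dict(lnL=-float(res.fun), lengths=lengths, kappa=kappa,
                omegas=omegas, x=res.x, converged=bool(res.success),
                free=free, n_edges=n_edges)


def fit_model(tree: GeneFamilyTree, aln: CodonAlignment,
              branch_classes: dict | None = None,
              class_order: list[str] | None = None,
              x0: np.ndarray | None = None):
    """Fit branch lengths, kappa and per-class omegas by ML.

    ``branch_classes`` maps clade keys (frozensets of leaf labels) to class
    labels; unlisted edges belong to the background class ``"bg"``.  Returns
    (CodonModelParams, lnL).  Deterministic: the optimiser start is the tree's
    own branch lengths with kappa 2 and omega 0.3 unless ``x0`` is supplied.
    """
    td = _TreeData(tree, aln)
    pi = genetics.f3x4_frequencies(td.sequences)
    if class_order is None:
        class_order = sorted({"bg", *(branch_classes or {}).values()})
    class_ids = td.edge_class_ids(branch_classes or {}, class_order)
    fit = _fit(td, pi, class_ids, len(class_order), x0=x0)
    params = CodonModelParams(
        kappa=fit["kappa"],
        omega_by_class={c: float(w) for c, w in zip(class_order, fit["omegas"])},
        branch_lengths={td.clade_keys[k]: float(fit["lengths"][k])
                        for k in range(td.n_nodes) if k != td.root_index},
        codon_freqs=pi,
    )
    return params, fit["lnL"]


# ---------------------------------------------------------------------------
# duplication LRTs


def _postduplication_structure(gft: GeneFamilyTree, species: str):
    """Paralogs of ``species``, their MRCA (the duplication node) and the
    clade keys of every edge strictly below it."""
    paralogs = gft.genes_of(species)
    if len(paralogs) < 2:
        raise ValueError(f"{species} has fewer than 2 paralogs")
    taxa = [gft.tree.taxon_namespace.get_taxon(l) for l in paralogs]
    mrca = gft.tree.mrca(taxa=taxa)
    postdup = [frozenset(lf.taxon.label for lf in nd.leaf_iter())
               for nd in mrca.preorder_iter() if nd is not mrca]
    return paralogs, mrca, postdup


def _nested_lrt(gft, aln, null_classes, null_order, alt_classes, alt_order,
                df, family_id="", species=""):
    td = _TreeData(gft, aln)
    pi = genetics.f3x4_frequencies(td.sequences)

    null_ids = td.edge_class_ids(null_classes, null_order)
    fit0 = _fit(td, pi, null_ids, len(null_order))

    # warm-start the alternative at the null optimum (guarantees nesting up
    # to optimiser tolerance), expanding the omega vector by class
    n_edges = fit0["n_edges"]
    null_w = dict(zip(null_order, fit0["omegas"]))
    x0 = np.concatenate([
        fit0["x"][:n_edges + 1],
        [math.log(max(null_w.get(_parent_class(c, null_order), 0.3), 1e-4))
         for c in alt_order],
    ])
    alt_ids = td.edge_class_ids(alt_classes, alt_order)
    fit1 = _fit(td, pi, alt_ids, len(alt_order), x0=x0)

    stat = max(2.0 * (fit1["lnL"] - fit0["lnL"]), 0.0)
    return LRTResult(
        lnL_null=fit0["lnL"], lnL_alt=fit1["lnL"], statistic=stat, df=df,
        p_raw=chi2_upper_tail(stat, df),
        omega_null=dict(zip(null_order, map(float, fit0["omegas"]))),
        omega_alt=dict(zip(alt_order, map(float, fit1["omegas"]))),
        family_id=family_id, species=species,
    )


def _parent_class(alt_class: str, null_order: list[str]) -> str:
    """Which null class an alternative class refines (bg stays bg; every
    foreground refinement starts from the shared foreground omega)."""
    if alt_class in null_order:
        return alt_class
    return null_order[-1] if len(null_order) > 1 else null_order[0]


def asymmetry_test(gft: GeneFamilyTree, aln: CodonAlignment,
                   duplicated_species: str) -> LRTResult:
    """LRT for unequal paralog rates (no dS filter is applied here).

    Null: omega0 background + shared paralog omega1; alternative: one omega
    per paralog terminal branch (internal post-duplication edges, if any,
    stay with the first paralog class); df = #paralogs - 1.
    """
    paralogs, _, postdup = _postduplication_structure(gft, duplicated_species)
    null_classes = {key: "dup" for key in postdup}
    alt_classes = {}
    for k, key in enumerate(postdup):
        if len(key) == 1:
            label = next(iter(key))
            alt_classes[key] = f"p{paralogs.index(label) + 1}"
        else:
            alt_classes[key] = "p1"
    alt_order = ["bg"] + [f"p{i + 1}" for i in range(len(paralogs))]
    return _nested_lrt(gft, aln, null_classes, ["bg", "dup"],
                       alt_classes, alt_order, df=len(paralogs) - 1,
                       family_id=gft.family_id, species=duplicated_species)


def acceleration_test(gft: GeneFamilyTree, aln: CodonAlignment,
                      duplicated_species: str) -> LRTResult:
    """LRT for a post-duplication rate shift.

    Null: one omega0 on all branches; alternative: omega0 plus a shared
    post-duplication omega1; df = 1.  Direction is 'faster' when
    omega1-hat > omega0-hat.
    """
    _, _, postdup = _postduplication_structure(gft, duplicated_species)
    alt_classes = {key: "dup" for key in postdup}
    res = _nested_lrt(gft, aln, {}, ["bg"], alt_classes, ["bg", "dup"], df=1,
                      family_id=gft.family_id, species=duplicated_species)
    res.direction = ("faster" if res.omega_alt["dup"] > res.omega_alt["bg"]
                     else "slower")
    return res


# ---------------------------------------------------------------------------
# meta-analysis helpers


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_combine(pvalues) -> tuple[float, int, float]:
    """Fisher's method: (-2 sum ln p, 2k, chi-square upper tail)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    stat = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return stat, df, chi2_upper_tail(stat, df)


def chi2_upper_tail(statistic: float, df: int) -> float:
    if statistic < 0 or df < 1:
        raise ValueError("need statistic >= 0 and df >= 1")
    return float(chi2.sf(statistic, df))


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p (sum of outcomes no more probable than k)."""
    if n <= 0 or not 0 <= k <= n:
        raise ValueError("need n >= 1 and 0 <= k <= n")
    return float(binomtest(k, n, p0).pvalue)
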