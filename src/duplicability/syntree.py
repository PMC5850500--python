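"""Synthetic primate gene-family generator.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without any external data:

* a fixed six-species catarrhine topology
  ``(((((human,chimp),gorilla),orangutan),gibbon),macaque)`` with branch
  lengths in expected substitutions per codon, loosely calibrated so the
  macaque–gibbon synonymous divergence lands around dS ~ 0.09;
* a minority class (default 5%) of families carrying one recent great-ape
  duplication, placed uniformly along a randomly chosen great-ape terminal
  branch (so the inter-paralog distance is smaller than either paralog's
  distance to gibbon, by construction);
* per-family dN/dS drawn log-normally with class medians 0.36 (duplicable)
  and 0.27 (singleton);
* codon sequences evolved along the gene tree under the GY94-style model
  (matrix-exponential transition probabilities, no indels), root state drawn
  from the family's F3x4-style stationary frequencies with a per-family GC3
  level;
* covariates (expression, CDS length, genomic length) correlated with the
  family's true omega: expression strongly negative (Spearman ~ -0.35), CDS
  length weakly negative (~ -0.1), plus small class offsets (duplicable
  genes slightly more expressed and shorter).

Reproducibility: one root seed; the random stream of family *i* is derived
by counter-based spawning (``SeedSequence(seed, spawn_key=(i,))``) so any
family can be regenerated in isolation, and identical seed + config gives a
byte-identical dataset.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import genetics, gy94
from .codonrates import CodonAlignment
from .treeclass import GREAT_APES, GeneFamilyTree, make_label

#: default species tree; branch lengths in expected substitutions/codon,
#: proportional to rough divergence times (rate 2.8e-3 subs/codon/My) so the
#: macaque-gibbon path is 0.14 subs/codon (dS ~ 0.09 at omega ~ 0.3)
DEFAULT_SPECIES_TREE = (
    "(((((human:0.0168,chimp:0.0168):0.0084,gorilla:0.0252):0.0196,"
    "orangutan:0.0448):0.0112,gibbon:0.0560):0.0140,macaque:0.0700);"
)

# position-specific nucleotide frequencies (A, C, G, T) for codon positions
# 1 and 2, loosely mammalian; position 3 is set per family from its GC3
_POS1_FREQS = (0.27, 0.23, 0.32, 0.18)
_POS2_FREQS = (0.31, 0.23, 0.19, 0.27)


@dataclass
class SimulationConfig:
    """Free parameters of the generator (defaults are the study conditions)."""

    n_families: int = 400
    fraction_duplicable: float = 0.05
    omega_median_singleton: float = 0.27
    omega_median_duplicable: float = 0.36
    sigma_log_omega: float = 0.30
    kappa: float = 3.0
    species_tree: str = DEFAULT_SPECIES_TREE
    dup_time_range: tuple[float, float] = (0.1, 0.9)
    paralogs_per_duplication: int = 2
    dup_omega_factor: float = 1.0   # post-duplication omega multiplier
    # CDS length: log10 of length in bp
    log10_cds_mean: float = 3.20
    log10_cds_sd: float = 0.25
    log10_cds_offset_duplicable: float = -0.14
    r_omega_cds: float = 0.105      # latent Pearson corr magnitude (negative)
    # expression, log2(RPKM)-like scale
    expr_mean: float = 2.6
    expr_sd: float = 1.8
    expr_offset_duplicable: float = 0.9
    r_omega_expr: float = 0.365
    # genomic length: log10 expansion over the CDS
    glen_expansion_mean: float = 0.9
    glen_expansion_sd: float = 0.45
    r_omega_glen: float = 0.06
    # GC content at third codon positions, per family
    gc3_mean: float = 0.56
    gc3_sd: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.fraction_duplicable <= 1.0:
            raise ValueError("fraction_duplicable must lie in [0, 1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.sigma_log_omega < 0 or self.log10_cds_sd < 0 or self.expr_sd < 0:
            raise ValueError("scale parameters must be >= 0")
        lo, hi = self.dup_time_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("dup_time_range must satisfy 0 <= lo < hi <= 1")
        if self.paralogs_per_duplication < 2:
            raise ValueError("paralogs_per_duplication must be >= 2")
        for r in (self.r_omega_cds, self.r_omega_expr, self.r_omega_glen):
            if not 0.0 <= r < 1.0:
                raise ValueError("correlation magnitudes must lie in [0, 1)")
        _parse_species_tree(self.species_tree)  # raises on bad newick/lengths


@dataclass
class SyntheticDataset:
    families: list[GeneFamilyTree]
    alignments: dict[str, CodonAlignment]
    covariates: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


# ---------------------------------------------------------------------------
# species-tree plumbing


class _Node:
    __slots__ = ("name", "length", "children", "postdup")

    def __init__(self, name=None, length=0.0, children=None, postdup=False):
        self.name = name
        self.length = length
        self.children = children or []
        self.postdup = postdup


def _parse_species_tree(newick: str) -> _Node:
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)

    def convert(nd):
        length = nd.edge.length or 0.0
        if length < 0:
            raise ValueError("species-tree branch lengths must be >= 0")
        if nd.is_leaf():
            return _Node(name=nd.taxon.label, length=length)
        return _Node(length=length, children=[convert(c) for c in nd.child_nodes()])

    root = convert(tree.seed_node)
    leaves = set()

    def collect(nd):
        if nd.name:
            leaves.add(nd.name)
        for c in nd.children:
            collect(c)

    collect(root)
    missing = {"human", "chimp", "gorilla", "orangutan", "gibbon", "macaque"} - leaves
    if missing:
        raise ValueError(f"species tree missing {sorted(missing)}")
    return root


def _insert_duplication(root: _Node, species: str, u: float, n_paralogs: int,
                        family_id: str) -> _Node:
    """Replace the terminal branch of ``species`` by a duplication at
    fraction ``u`` of the branch (from its parent), yielding ``n_paralogs``
    leaf copies; extra copies beyond two arise from successive splits halfway
    along the remaining time."""

    def make_paralogs(remaining: float, k: int, next_id: list[int]) -> _Node:
        if k == 1:
            gid = f"{family_id}_{species[:3]}{next_id[0]}"
            next_id[0] += 1
            return _Node(name=make_label(species, gid), length=remaining,
                         postdup=True)
        half = 0.5 * remaining
        left = make_paralogs(half, 1, next_id)
        right = make_paralogs(half, k - 1, next_id)
        return _Node(length=half, children=[left, right], postdup=True)

    def walk(nd: _Node) -> _Node:
        if nd.name == make_label(species, f"{family_id}_{species[:3]}"):
            remaining = (1.0 - u) * nd.length
            counter = [1]
            a = make_paralogs(remaining, 1, counter)
            b = make_paralogs(remaining, n_paralogs - 1, counter)
            return _Node(length=u * nd.length, children=[a, b], postdup=False)
        nd.children = [walk(c) for c in nd.children]
        return nd

    return walk(root)


def _gene_tree(cfg: SimulationConfig, family_id: str, dup_species: str | None,
               u: float | None) -> _Node:
    root = _parse_species_tree(cfg.species_tree)

    def label_leaves(nd: _Node):
        if nd.name and not nd.children:
            nd.name = make_label(nd.name, f"{family_id}_{nd.name[:3]}")
        for c in nd.children:
            label_leaves(c)

    label_leaves(root)
    if dup_species is not None:
        root = _insert_duplication(root, dup_species, u,
                                   cfg.paralogs_per_duplication, family_id)
    return root


def _to_newick(nd: _Node) -> str:
    if not nd.children:
        return f"{nd.name}:{nd.length:.10g}"
    inner = ",".join(_to_newick(c) for c in nd.children)
    return f"({inner}):{nd.length:.10g}" if nd.length else f"({inner})"


# ---------------------------------------------------------------------------
# sequence evolution


def _evolve(node: _Node, states: np.ndarray, spectra: dict[bool, gy94.SpectralQ],
            rng: np.random.Generator, out: dict[str, np.ndarray]) -> None:
    for child in node.children:
        P = spectra[child.postdup].transition_matrix(child.length)
        child_states = np.empty_like(states)
        for s in np.unique(states):
            idx = np.flatnonzero(states == s)
            child_states[idx] = rng.choice(genetics.N_CODONS, size=idx.size, p=P[s])
        if child.children:
            _evolve(child, child_states, spectra, rng, out)
        else:
            out[child.name] = child_states


def _decode(states: np.ndarray) -> str:
    return "".join(genetics.SENSE_CODONS[s] for s in states)


def simulate_family(cfg: SimulationConfig, class_label: str,
                    rng: np.random.Generator, family_id: str):
    """Simulate one gene family: (tree, alignment, truth record)."""
    if class_label not in ("singleton", "duplicable"):
        raise ValueError(f"unknown class label {class_label!r}")
    cfg.validate()

    z_omega = float(rng.standard_normal())
    median = (cfg.omega_median_duplicable if class_label == "duplicable"
              else cfg.omega_median_singleton)
    omega = float(np.clip(math.exp(math.log(median) + cfg.sigma_log_omega * z_omega),
                          1e-3, 10.0))

    # CDS length, negatively tied to omega through the shared latent z
    offset = cfg.log10_cds_offset_duplicable if class_label == "duplicable" else 0.0
    r = cfg.r_omega_cds
    z_len = -r * z_omega + math.sqrt(1.0 - r * r) * float(rng.standard_normal())
    log10_cds = cfg.log10_cds_mean + offset + cfg.log10_cds_sd * z_len
    n_codons = max(int(round((10.0 ** log10_cds) / 3.0)), 30)

    gc3 = float(np.clip(rng.normal(cfg.gc3_mean, cfg.gc3_sd), 0.25, 0.90))
    pos3 = ((1 - gc3) / 2, gc3 / 2, gc3 / 2, (1 - gc3) / 2)
    pi = genetics.f3x4_from_position_freqs(
        np.array([_POS1_FREQS, _POS2_FREQS, pos3]))

    dup_species = None
    u = None
    if class_label == "duplicable":
        dup_species = GREAT_APES[int(rng.integers(len(GREAT_APES)))]
        lo, hi = cfg.dup_time_range
        u = float(rng.uniform(lo, hi))
    root = _gene_tree(cfg, family_id, dup_species, u)

    omega_post = float(np.clip(omega * cfg.dup_omega_factor, 1e-3, 60.0))
    spectra = {False: gy94.spectral(gy94.rate_matrix(cfg.kappa, omega, pi), pi)}
    spectra[True] = (spectra[False] if omega_post == omega else
                     gy94.spectral(gy94.rate_matrix(cfg.kappa, omega_post, pi), pi))

    root_states = rng.choice(genetics.N_CODONS, size=n_codons, p=pi)
    leaf_states: dict[str, np.ndarray] = {}
    _evolve(root, root_states, spectra, rng, leaf_states)

    from .treeclass import split_label
    sequences = {split_label(lbl): _decode(states)
                 for lbl, states in sorted(leaf_states.items())}
    aln = CodonAlignment(sequences)
    tree = GeneFamilyTree.from_newick(_to_newick(root) + ";", family_id)

    truth = dict(family_id=family_id, group=class_label, omega_true=omega,
                 omega_postdup_true=(omega_post if dup_species else omega),
                 z_omega=z_omega, dup_species=dup_species or "",
                 dup_time_fraction=(u if u is not None else float("nan")),
                 n_codons=n_codons, gc3_target=100.0 * gc3)
    return tree, aln, truth


def simulate_covariates(cfg: SimulationConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-family covariates linked to the true omega via its latent z.

    Expression (log2(RPKM)-like, floored at 0) correlates negatively with
    omega and is slightly higher in the duplicable class; genomic length
    expands the CDS by a log10 factor with only a weak omega link.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1 << 20,)))
    rows = []
    for rec in truth.sort_values("family_id").itertuples():
        dup = rec.group == "duplicable"
        re_ = cfg.r_omega_expr
        z_e = -re_ * rec.z_omega + math.sqrt(1 - re_ * re_) * float(rng.standard_normal())
        expr = max(cfg.expr_mean + (cfg.expr_offset_duplicable if dup else 0.0)
                   + cfg.expr_sd * z_e, 0.0)
        rg = cfg.r_omega_glen
        z_g = -rg * rec.z_omega + math.sqrt(1 - rg * rg) * float(rng.standard_normal())
        cds_bp = 3 * rec.n_codons
        expansion = max(cfg.glen_expansion_mean + cfg.glen_expansion_sd * z_g, 0.0)
        rows.append(dict(
            gene_id=f"{rec.family_id}_mac",
            family_id=rec.family_id,
            group=rec.group,
            expression=expr,
            cds_length=cds_bp,
            genomic_length=int(round(cds_bp * 10.0 ** expansion)),
        ))
    return pd.DataFrame(rows)


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate the full dataset for one configuration."""
    cfg.validate()
    width = max(4, len(str(cfg.n_families)))
    class_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
    # exact class sizes (round(f*n) duplicable), positions randomised
    n_dup = int(round(cfg.fraction_duplicable * cfg.n_families))
    labels = np.array(["duplicable"] * n_dup
                      + ["singleton"] * (cfg.n_families - n_dup))
    class_rng.shuffle(labels)
    families, alignments, truth_rows = [], {}, []
    for i in range(cfg.n_families):
        family_id = f"fam{i + 1:0{width}d}"
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(i + 1,)))
        tree, aln, rec = simulate_family(cfg, str(labels[i]), rng, family_id)
        families.append(tree)
        alignments[family_id] = aln
        truth_rows.append(rec)
    truth = pd.DataFrame(truth_rows)
    covariates = simulate_covariates(cfg, truth)
    return SyntheticDataset(families=families, alignments=alignments,
                            covariates=covariates, truth=truth, config=cfg)


def evolve_alignment(gft: GeneFamilyTree, n_codons: int, kappa: float,
                     omega: float, pi: np.ndarray, rng: np.random.Generator,
                     omega_overrides: dict | None = None) -> CodonAlignment:
    """Evolve a codon alignment along an arbitrary gene tree.

    ``omega_overrides`` maps clade keys (frozensets of leaf labels) to the
    omega that applies on the edge subtending that clade; unlisted edges use
    the background ``omega``.  The root state is drawn from ``pi``.
    """
    from .treeclass import split_label

    spectra: dict[float, gy94.SpectralQ] = {}

    def spec(w: float) -> gy94.SpectralQ:
        if w not in spectra:
            spectra[w] = gy94.spectral(gy94.rate_matrix(kappa, w, pi), pi)
        return spectra[w]

    overrides = omega_overrides or {}
    out: dict[tuple[str, str], str] = {}

    def walk(node, states: np.ndarray):
        for child in node.child_nodes():
            clade = frozenset(lf.taxon.label for lf in child.leaf_iter())
            w = overrides.get(clade, omega)
            P = spec(w).transition_matrix(float(child.edge.length or 0.0))
            child_states = np.empty_like(states)
            for s in np.unique(states):
                idx = np.flatnonzero(states == s)
                child_states[idx] = rng.choice(genetics.N_CODONS, size=idx.size, p=P[s])
            if child.is_leaf():
                out[split_label(child.taxon.label)] = _decode(child_states)
            else:
                walk(child, child_states)

    root_states = rng.choice(genetics.N_CODONS, size=n_codons, p=pi)
    root = gft.tree.seed_node
    if root.is_leaf():
        raise ValueError("degenerate single-leaf tree")
    walk(root, root_states)
    return CodonAlignment(out)


# ---------------------------------------------------------------------------
# on-disk form


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict:
    """Write Newick + FASTA per family plus covariate/truth TSVs; returns a
    manifest of relative paths and content checksums."""
    out = Path(out_dir)
    (out / "trees").mkdir(parents=True, exist_ok=True)
    (out / "alignments").mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def record(rel: str, text: str):
        (out / rel).write_text(text)
        files[rel] = hashlib.sha256(text.encode()).hexdigest()

    for tree in ds.families:
        record(f"trees/{tree.family_id}.nwk", tree.to_newick())
    for fam_id in sorted(ds.alignments):
        aln = ds.alignments[fam_id]
        fasta = "".join(f">{sp}|{gid}\n{aln.sequences[(sp, gid)]}\n"
                        for sp, gid in aln.keys())
        record(f"alignments/{fam_id}.fasta", fasta)
    record("covariates.tsv", ds.covariates.to_csv(sep="\t", index=False))
    record("truth.tsv", ds.truth.to_csv(sep="\t", index=False))
    manifest = dict(n_families=len(ds.families), seed=ds.config.seed, files=files)
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def read_dataset(in_dir: str | Path) -> tuple[list[GeneFamilyTree], dict, pd.DataFrame, pd.DataFrame]:
    """Load a written dataset (trees, alignments, covariates, truth)."""
    from .treeclass import split_label

    root = Path(in_dir)
    families, alignments = [], {}
    for path in sorted((root / "trees").glob("*.nwk")):
        families.append(GeneFamilyTree.from_newick(path.read_text(), path.stem))
    for path in sorted((root / "alignments").glob("*.fasta")):
        seqs, label = {}, None
        for line in path.read_text().splitlines():
            if line.startswith(">"):
                label = split_label(line[1:].strip())
                seqs[label] = ""
            elif label is not None:
                seqs[label] += line.strip()
        alignments[path.stem] = CodonAlignment(seqs)
    covariates = pd.read_csv(root / "covariates.tsv", sep="\t")
    truth = pd.read_csv(root / "truth.tsv", sep="\t")
    return families, alignments, covariates, truth
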