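"""Pairwise dN/dS estimation between aligned coding sequences.

Two estimators are provided over the same codon alignment container:

* :func:`pairwise_dnds_ml` — maximum likelihood under the GY94-style codon
  model with F3x4 frequencies estimated empirically from the pair (the
  pairwise mode of codeml-type analyses); dN and dS are derived from the
  fitted (t, kappa, omega) by the standard flux decomposition.
* :func:`pairwise_dnds_ng86` — the Nei–Gojobori (1986) counting method with
  Jukes–Cantor correction, kept deliberately independent of the likelihood
  machinery so it can serve as an oracle for the ML route.

Codon columns containing a gap or non-ACGT symbol in either sequence are
dropped (pairwise deletion).  In-frame stop codons raise an error.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from . import genetics, gy94
from .genetics import (AMINO_ACID, CODON_INDEX, GAP_CODON, NUCLEOTIDES,
                       SENSE_CODONS, STOP_CODONS)

SeqKey = tuple[str, str]  # (species, gene_id)


@dataclass
class CodonAlignment:
    """In-frame aligned codon sequences keyed by (species, gene_id)."""

    sequences: dict[SeqKey, str]

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        if lengths and next(iter(lengths)) % 3 != 0:
            raise ValueError("alignment length not divisible by 3")
        for key, seq in self.sequences.items():
            for k in range(0, len(seq), 3):
                codon = seq[k:k + 3].upper()
                if codon in STOP_CODONS:
                    raise ValueError(f"in-frame stop codon in {key} at codon {k // 3}")
                if "-" in codon and codon != GAP_CODON:
                    raise ValueError(f"partial-codon gap in {key} at codon {k // 3}")

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.sequences.values()))) // 3 if self.sequences else 0

    def keys(self) -> list[SeqKey]:
        return sorted(self.sequences)

    def by_label(self, label: str) -> str:
        from .treeclass import split_label
        return self.sequences[split_label(label)]

    def species_sequence(self, species: str) -> str:
        hits = [s for (sp, _), s in self.sequences.items() if sp == species]
        if len(hits) != 1:
            raise KeyError(f"expected exactly one {species} sequence, found {len(hits)}")
        return hits[0]

    def subset(self, keys) -> "CodonAlignment":
        return CodonAlignment({k: self.sequences[k] for k in keys})


@dataclass
class RateEstimate:
    """Per-pair substitution-rate estimate."""

    dN: float
    dS: float
    omega: float | None  # None when undefined (dS == 0)
    kappa: float | None
    t: float
    logL: float | None
    method: str  # "ML_F3x4" | "NG86"
    converged: bool = True
    saturated: bool = False
    pair: tuple[str, str] | None = None

    @property
    def omega_defined(self) -> bool:
        return self.omega is not None and math.isfinite(self.omega)


# ---------------------------------------------------------------------------
# back-translation


def backtranslate(protein_alignment: dict[SeqKey, str],
                  cds_map: dict[SeqKey, str]) -> CodonAlignment:
    """Map a gapped protein alignment back onto its source codons.

    Every amino acid is replaced by the codon that produced it (verified by
    translation under the standard code); every protein gap becomes '---'.
    """
    out: dict[SeqKey, str] = {}
    for key, prot in protein_alignment.items():
        cds = cds_map[key].upper()
        if len(cds) % 3 != 0:
            raise ValueError(f"{key}: CDS length not divisible by 3")
        codons = genetics.codons_of(cds)
        # trailing stop codons are permitted on the CDS, not in the alignment
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        ungapped = [aa for aa in prot if aa != "-"]
        if len(codons) != len(ungapped):
            raise ValueError(f"{key}: CDS ({len(codons)} codons) does not match "
                             f"ungapped protein ({len(ungapped)} residues)")
        pieces, k = [], 0
        for pos, aa in enumerate(prot):
            if aa == "-":
                pieces.append(GAP_CODON)
                continue
            codon = codons[k]
            if codon not in CODON_INDEX:
                raise ValueError(f"{key}: untranslatable codon {codon!r} at residue {k}")
            if AMINO_ACID[codon] != aa.upper():
                raise ValueError(f"{key}: codon {codon} translates to "
                                 f"{AMINO_ACID[codon]}, alignment has {aa} at column {pos}")
            pieces.append(codon)
            k += 1
        out[key] = "".join(pieces)
    return CodonAlignment(out)


# ---------------------------------------------------------------------------
# pairwise maximum likelihood (GY94 + F3x4)


def _pair_patterns(aln: CodonAlignment):
    """Shared ungapped codon columns of a 2-sequence alignment, compressed to
    unique (state_i, state_j) patterns with counts."""
    keys = aln.keys()
    if len(keys) != 2:
        raise ValueError("pairwise estimator needs exactly 2 sequences")
    a = genetics.encode_codons(aln.sequences[keys[0]])
    b = genetics.encode_codons(aln.sequences[keys[1]])
    usable = (a >= 0) & (b >= 0)
    if not usable.any():
        raise ValueError("no shared ungapped codon columns")
    a, b = a[usable], b[usable]
    codes, counts = np.unique(a * genetics.N_CODONS + b, return_counts=True)
    return codes // genetics.N_CODONS, codes % genetics.N_CODONS, counts, keys


def _pair_loglik(t: float, kappa: float, omega: float, pi: np.ndarray,
                 ia: np.ndarray, ib: np.ndarray, counts: np.ndarray,
                 cache: dict | None = None) -> float:
    key = (kappa, omega)
    if cache is not None and key in cache:
        sq = cache[key]
    else:
        sq = gy94.spectral(gy94.rate_matrix(kappa, omega, pi), pi)
        if cache is not None:
            if len(cache) > 512:
                cache.clear()
            cache[key] = sq
    P = sq.transition_matrix(t)
    site_lik = pi[ia] * P[ia, ib]
    return float(counts @ np.log(np.maximum(site_lik, 1e-300)))


_BOUNDS = [(math.log(1e-6), math.log(20.0)),   # log t
           (math.log(0.05), math.log(50.0)),   # log kappa
           (math.log(1e-4), math.log(60.0))]   # log omega

# fixed multiplicative perturbations of the heuristic start (deterministic
# restart schedule)
_RESTART_FACTORS = [(1.0, 1.0, 1.0), (2.0, 0.5, 3.0), (0.5, 2.0, 0.2)]


def pairwise_dnds_ml(aln: CodonAlignment) -> RateEstimate:
    """ML (t, kappa, omega) for one sequence pair under GY94 + F3x4."""
    ia, ib, counts, keys = _pair_patterns(aln)
    seqs = [aln.sequences[k] for k in keys]
    pi = genetics.f3x4_frequencies(seqs)

    p_diff = float(counts[ia != ib].sum()) / float(counts.sum())
    t0 = max(3.0 * p_diff, 1e-3)  # crude subs/codon start
    cache: dict = {}

    def nll(x):
        t, kappa, omega = np.exp(x)
        return -_pair_loglik(t, kappa, omega, pi, ia, ib, counts, cache=cache)

    best = None
    for ft, fk, fw in _RESTART_FACTORS:
        x0 = np.log([min(t0 * ft, 10.0), 2.0 * fk, 0.3 * fw])
        res = minimize(nll, x0, method="L-BFGS-B", bounds=_BOUNDS,
                       options=dict(maxiter=500, ftol=1e-12))
        if best is None or res.fun < best.fun:
            best = res
    t, kappa, omega = np.exp(best.x)
    dN, dS = gy94.dn_ds_from_params(t, kappa, omega, pi)
    return RateEstimate(dN=dN, dS=dS, omega=float(omega), kappa=float(kappa),
                        t=float(t), logL=-float(best.fun), method="ML_F3x4",
                        converged=bool(best.success),
                        pair=("|".join(keys[0]), "|".join(keys[1])))


def pairwise_loglik(aln: CodonAlignment, t: float, kappa: float, omega: float,
                    pi: np.ndarray | None = None) -> float:
    """Pairwise log-likelihood at fixed parameters (cross-module oracle)."""
    ia, ib, counts, keys = _pair_patterns(aln)
    if pi is None:
        pi = genetics.f3x4_frequencies([aln.sequences[k] for k in keys])
    return _pair_loglik(t, kappa, omega, pi, ia, ib, counts)


# ---------------------------------------------------------------------------
# Nei–Gojobori 1986 counting oracle


def _syn_site_fraction() -> dict[str, float]:
    """Synonymous site count per codon (mutations to stops = nonsynonymous)."""
    out = {}
    for codon in SENSE_CODONS:
        s = 0.0
        for pos in range(3):
            for nt in NUCLEOTIDES:
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1:]
                if alt not in STOP_CODONS and AMINO_ACID[alt] == AMINO_ACID[codon]:
                    s += 1.0 / 3.0
        out[codon] = s
    return out


_SYN_SITES = _syn_site_fraction()


def _pathway_changes(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous step counts over all mutational
    pathways between two codons, excluding pathways through stop codons."""
    positions = [k for k in range(3) if c1[k] != c2[k]]
    syn_tot = non_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(positions):
        cur = c1
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            steps.append((cur, nxt))
            cur = nxt
        if not ok:
            continue
        n_paths += 1
        for a, b in steps:
            if AMINO_ACID[a] == AMINO_ACID[b]:
                syn_tot += 1
            else:
                non_tot += 1
    if n_paths == 0:
        # all pathways blocked by stops: classify every changed position as
        # nonsynonymous (conservative; vanishingly rare in real data)
        return 0.0, float(len(positions))
    return syn_tot / n_paths, non_tot / n_paths


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def pairwise_dnds_ng86(aln: CodonAlignment) -> RateEstimate:
    """NG86 dN/dS with Jukes–Cantor multiple-hit correction."""
    keys = aln.keys()
    if len(keys) != 2:
        raise ValueError("pairwise estimator needs exactly 2 sequences")
    s1 = genetics.codons_of(aln.sequences[keys[0]].upper())
    s2 = genetics.codons_of(aln.sequences[keys[1]].upper())
    S = Sd = Nd = 0.0
    n_cols = 0
    for c1, c2 in zip(s1, s2):
        if c1 not in CODON_INDEX or c2 not in CODON_INDEX:
            continue  # pairwise deletion
        n_cols += 1
        S += 0.5 * (_SYN_SITES[c1] + _SYN_SITES[c2])
        if c1 != c2:
            sd, nd = _pathway_changes(c1, c2)
            Sd += sd
            Nd += nd
    if n_cols == 0:
        raise ValueError("no shared ungapped codon columns")
    N = 3.0 * n_cols - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jukes_cantor(pS)
    dN = _jukes_cantor(pN)
    saturated = not (math.isfinite(dS) and math.isfinite(dN))
    omega = None
    if not saturated and dS > 0:
        omega = dN / dS
    t = (dS * S + dN * N) / n_cols if not saturated else math.inf
    return RateEstimate(dN=dN, dS=dS, omega=omega, kappa=None, t=t, logL=None,
                        method="NG86", saturated=saturated,
                        pair=("|".join(keys[0]), "|".join(keys[1])))


# ---------------------------------------------------------------------------
# filters and summaries


def rate_filter(estimates: list[RateEstimate], ds_min: float = 0.01,
                omega_max: float = 10.0):
    """Apply the low-dS / high-omega exclusion rule.

    Retains estimates with dS >= ds_min, a defined omega, and omega <=
    omega_max; everything else is logged with its exclusion reason.
    """
    retained, exclusions = [], []
    for est in estimates:
        if est.saturated:
            exclusions.append((est, "saturated"))
        elif not est.omega_defined:
            exclusions.append((est, "undefined_omega"))
        elif est.dS < ds_min:
            exclusions.append((est, "low_dS"))
        elif est.omega > omega_max:
            exclusions.append((est, "high_omega"))
        else:
            retained.append(est)
    return retained, exclusions


def paralog_mean_rate(family_id: str,
                      per_paralog_estimates: list[RateEstimate]) -> RateEstimate:
    """Arithmetic mean of dN, dS, omega over the paralog–macaque pairs of one
    family (the family-level post-duplication rate)."""
    if not per_paralog_estimates:
        raise ValueError(f"{family_id}: no paralog estimates")
    usable = [e for e in per_paralog_estimates if e.omega_defined]
    if not usable:
        raise ValueError(f"{family_id}: no defined omega among paralog estimates")
    return RateEstimate(
        dN=float(np.mean([e.dN for e in usable])),
        dS=float(np.mean([e.dS for e in usable])),
        omega=float(np.mean([e.omega for e in usable])),
        kappa=None,
        t=float(np.mean([e.t for e in usable])),
        logL=None,
        method=usable[0].method,
        pair=(family_id, "paralog_mean"),
    )


def gc3(aln: CodonAlignment, species_pair: tuple[str, str] = ("macaque", "gibbon")) -> float:
    """Mean GC3 (%) of the two named species' sequences."""
    values = [genetics.gc3_percent(aln.species_sequence(sp)) for sp in species_pair]
    return float(np.mean(values))
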