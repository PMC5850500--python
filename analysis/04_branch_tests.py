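#!/usr/bin/env python
"""Branch-model LRTs on the duplicable families.

Asymmetry: do the paralogs of a duplicated species evolve at different
rates?  (The dS filter is dropped here so very recent duplications are not
excluded.)  Acceleration: did omega change post-duplication?  (Full dS/omega
filter applied.)  Per-test results are FDR-corrected; the tests are then
combined en masse with Fisher's method, and the faster/slower split is
checked against 50:50 with an exact binomial test.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from duplicability import branchlik, syntree, treeclass


def run_block(which, families, alignments, rates):
    rows = []
    for fam in families:
        rate = rates.loc[rates["family_id"] == fam.family_id]
        if rate.empty or rate.iloc[0]["group"] != "duplicable":
            continue
        if rate.iloc[0]["omega"] > 10.0:
            continue
        if which == "acceleration" and rate.iloc[0]["dS"] < 0.01:
            continue
        oc = treeclass.classify_family(fam)
        aln = alignments[fam.family_id]
        for species in oc.duplicated_species:
            test = (branchlik.asymmetry_test if which == "asymmetry"
                    else branchlik.acceleration_test)
            rows.append(test(fam, aln, species))
    if rows:
        for r, q in zip(rows, branchlik.bh_fdr([r.p_raw for r in rows])):
            r.p_fdr = float(q)
    return rows


def summarise(which, rows):
    if not rows:
        print(f"{which}: nothing to test")
        return
    p = [r.p_raw for r in rows]
    chi2, df, pc = branchlik.fisher_combine(np.clip(p, 1e-300, 1.0))
    print(f"{which}: {len(rows)} tests; {sum(x < 0.05 for x in p)} raw p<0.05; "
          f"{sum(r.p_fdr < 0.05 for r in rows)} FDR-significant; "
          f"Fisher chi2={chi2:.2f} (df={df}, p={pc:.3g})")
    if which == "acceleration":
        faster = [r for r in rows if r.direction == "faster"]
        pb = branchlik.binomial_two_sided(len(faster), len(rows))
        print(f"  faster/slower: {len(faster)}/{len(rows) - len(faster)} "
              f"(binomial two-sided p={pb:.3g})")
        if faster:
            chi2f, dff, pf = branchlik.fisher_combine(
                np.clip([r.p_raw for r in faster], 1e-300, 1.0))
            print(f"  Fisher over faster subset: chi2={chi2f:.2f} "
                  f"(df={dff}, p={pf:.3g})")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/dataset"))
    ap.add_argument("--rates", type=Path, default=Path("results/rates.tsv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    families, alignments, _, _ = syntree.read_dataset(args.data)
    rates = pd.read_csv(args.rates, sep="\t")

    for which in ("asymmetry", "acceleration"):
        rows = run_block(which, families, alignments, rates)
        summarise(which, rows)
        df = pd.DataFrame([dict(
            family_id=r.family_id, species=r.species, lnL0=r.lnL_null,
            lnL1=r.lnL_alt, stat=r.statistic, df=r.df, p_raw=r.p_raw,
            p_fdr=r.p_fdr, direction=r.direction,
            omega0=r.omega_alt.get("bg"),
            omega_fg=";".join(f"{k}={v:.4g}" for k, v in r.omega_alt.items()
                              if k != "bg"),
        ) for r in rows])
        out = args.out_dir / f"lrt_{which}.tsv"
        out.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(out, sep="\t", index=False, float_format="%.6g")
        print(f"wrote {out}")


if __name__ == "__main__":
    main()
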