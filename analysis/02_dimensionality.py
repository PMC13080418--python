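#!/usr/bin/env python
"""Stage 1-2: how large is the first component, and how many factors?

Estimates the pairwise-complete polychoric correlation matrix of the
pretreatment items, reports the share of covariance explained by the first
principal component and the first/second ratio, then runs column-
permutation parallel analysis on the pretreatment responses (polychoric)
and on the item change scores (Pearson). Writes the scree tables under
results/dimensionality/.
"""

import argparse
from pathlib import Path

from margirt.dimensionality import (
    change_scores,
    explained_covariance,
    parallel_analysis,
)
from margirt.polychoric import polychoric_matrix
from margirt.synthetic import default_registry_spec
from margirt.types import ResponseMatrix


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--n-random", type=int, default=100)
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--out", type=Path, default=Path("results/dimensionality"))
    args = ap.parse_args()

    specs, _ = default_registry_spec()
    pre = ResponseMatrix.from_csv(args.cohort / "pretreatment.csv", specs)
    post = ResponseMatrix.from_csv(args.cohort / "posttreatment.csv", specs)
    args.out.mkdir(parents=True, exist_ok=True)

    poly = polychoric_matrix(pre)
    vd = explained_covariance(poly.matrix())
    vd.scree_table().to_csv(args.out / "scree_pretreatment.csv", index=False)
    print(f"pretreatment: first PC explains {vd.pct_explained[0]:.1f}% of "
          f"covariance, {vd.ratio_first_to_second:.1f}x the second "
          f"({vd.pct_explained[1]:.1f}%)")

    pa = parallel_analysis(pre, n_random=args.n_random, seed=args.seed)
    print(f"parallel analysis (pretreatment, polychoric, "
          f"{args.n_random} permuted nulls): {pa.n_factors} factors")

    delta = change_scores(pre, post)
    vd_chg = explained_covariance(delta.corr(min_periods=2).to_numpy())
    vd_chg.scree_table().to_csv(args.out / "scree_change_scores.csv", index=False)
    pa_chg = parallel_analysis(delta, n_random=args.n_random,
                               seed=args.seed + 1, method="pearson")
    print(f"change scores: first PC {vd_chg.pct_explained[0]:.1f}%, "
          f"parallel analysis suggests {pa_chg.n_factors} factors")
    print(f"wrote scree tables to {args.out}/")


if __name__ == "__main__":
    main()
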