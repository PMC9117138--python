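#!/usr/bin/env python
"""Fit the parental-age models.

Identity-link negative-binomial regressions of (i) total dnSNV counts on
both parental ages, (ii) phased paternal/maternal counts on the matching
parent's age, and (iii) dnIndel counts; reports slopes, dispersions and
the paternal/maternal slope ratios.
"""

import json
from pathlib import Path

import pandas as pd

from hypermut.agemodel import (build_design, fit_nb_identity,
                               fit_phased_models, slope_ratio)
from hypermut.cohort import read_cohort

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    co = read_cohort(BASE / "cohort")
    tr = co.trios
    phased = pd.read_csv(BASE / "phased_counts.tsv", sep="\t")

    X = build_design(tr, ["father_age", "mother_age"])
    fit = fit_nb_identity(tr["n_snv"].to_numpy(), X,
                          names=["intercept", "father_age", "mother_age"])
    fit_ind = fit_nb_identity(tr["n_indel"].to_numpy(), X,
                              names=["intercept", "father_age",
                                     "mother_age"])
    fp, fm = fit_phased_models(phased["n_paternal"], phased["father_age"],
                               phased["n_maternal"], phased["mother_age"])

    out = {
        "snv": {"coef": dict(zip(fit.names, fit.params)),
                "se": dict(zip(fit.names, fit.se)),
                "theta": fit.theta, "pseudo_r2": fit.pseudo_r2},
        "indel": {"coef": dict(zip(fit_ind.names, fit_ind.params)),
                  "theta": fit_ind.theta},
        "phased_paternal_slope": fp.params[1],
        "phased_maternal_slope": fm.params[1],
        "snv_slope_ratio": slope_ratio(
            type("F", (), {"params": fit.params[[0, 1]]}),
            type("F", (), {"params": fit.params[[0, 2]]})),
    }
    (BASE / "age_models.json").write_text(json.dumps(out, indent=1))

    print("total dnSNVs ~ parental ages (identity-link NB):")
    print(fit.summary().round(4).to_string())
    print(f"dispersion theta = {fit.theta:.0f}")
    print(f"slope ratio paternal/maternal: {out['snv_slope_ratio']}")
    print(f"phased slopes: paternal {fp.params[1]:.2f}/yr, "
          f"maternal {fm.params[1]:.2f}/yr")
    print(f"indel slopes: paternal {fit_ind.params[1]:.3f}/yr, "
          f"maternal {fit_ind.params[2]:.3f}/yr")
    print(f"wrote {BASE / 'age_models.json'}")


if __name__ == "__main__":
    main()
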