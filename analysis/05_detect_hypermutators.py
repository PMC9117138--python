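#!/usr/bin/env python
"""Detect hypermutated children and screen out the artifact mode.

Runs the iterative outlier scan (identity-link NB age model, Bonferroni
at 0.05/N), screens every flagged child for the clustered-calls +
parental-LOH artifact, excludes artifacts and refits, then characterizes
each surviving hypermutator: per-type Poisson enrichments, phase bias,
low-VAF shift and transcriptional strand bias.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from hypermut.cohort import parental_genotype_bins, read_cohort
from hypermut.detect import (artifact_screen, characterize_hypermutator,
                             cohort_reference, excess_and_fold,
                             iterative_detection)

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    co = read_cohort(BASE / "cohort")
    phased = pd.read_csv(BASE / "phased_counts.tsv", sep="\t")

    def screen(flagged_ids):
        out = set()
        if not flagged_ids:
            return out
        bins = parental_genotype_bins(co, flagged_ids)
        for cid in flagged_ids:
            calls = co.dnms[co.dnms["child_id"] == cid]
            res = artifact_screen(calls, bins[bins["child_id"] == cid])
            if res["artifact"]:
                print(f"  artifact: {cid} (chrom {res['chrom']}, "
                      f"window {res['window']}, parent {res['parent']})")
                out.add(cid)
        return out

    reports, fit, excluded = iterative_detection(co.trios, screen)
    flagged = [r for r in reports if r.flagged]
    median = co.trios.loc[~co.trios["child_id"].isin(excluded),
                          "n_snv"].median()

    truth = co.trios.set_index("child_id")["etiology"]
    ref = cohort_reference(
        co.dnms[~co.dnms["child_id"].isin(excluded)],
        phased, n_children=len(co.trios) - len(excluded),
        n_flagged=max(len(flagged), 1))
    rows = []
    for rep in flagged:
        calls = co.dnms[co.dnms["child_id"] == rep.child_id]
        tphased = phased.set_index("trio_id").loc[
            rep.child_id.replace("child", "trio")]
        rep = characterize_hypermutator(
            rep, calls, int(tphased["n_paternal"]),
            int(tphased["n_maternal"]), ref)
        rep.excess, rep.fold = excess_and_fold(rep.observed, median)
        rows.append(rep)
        enr = {t: round(v["enrichment"], 1)
               for t, v in rep.type_enrichment.items()
               if v["enrichment"] is not None}
        print(f"{rep.child_id}: {rep.observed} dnSNVs "
              f"(expected {rep.expected:.0f}, fold {rep.fold}, "
              f"excess {rep.excess}, truth={truth[rep.child_id]})")
        print(f"  enrichment {enr}")
        print(f"  phase-bias p {rep.phase_bias_p:.2e}; "
              f"VAF-shift p {rep.vaf_shift_p:.2e}")

    (BASE / "hypermutators.json").write_text(json.dumps(
        [dataclasses.asdict(r) for r in rows], indent=1, default=str))
    (BASE / "artifact_exclusions.json").write_text(
        json.dumps(sorted(excluded)))
    print(f"\nexcluded artifacts: {sorted(excluded)}")
    print(f"flagged hypermutators: {len(rows)} "
          f"(threshold 0.05/{len(co.trios) - len(excluded)})")
    print(f"wrote {BASE / 'hypermutators.json'}")


if __name__ == "__main__":
    main()
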