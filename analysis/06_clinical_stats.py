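#!/usr/bin/env python
"""Clinical summary of the unrelated RYR2 mutation carriers.

Recomputes the carriers' QTc mean +/- sample SD, tabulates their cardiac
events, and counts distinct RYR2 candidate mutations across the family
and unrelated arms.
"""

import argparse
from pathlib import Path

import pandas as pd

from lqtex import curated
from lqtex.cohort_stats import event_tabulate, mean_sd

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

records = curated.RYR2_CLINICAL
qtc = [r.qtc for r in records]
mean, sd = mean_sd(qtc)
events = event_tabulate([r.event for r in records])
family_ryr2 = {m.cdna for m in curated.FAMILY_CANDIDATES if m.gene == "RYR2"}
unrelated_ryr2 = {m.cdna for m in curated.UNRELATED_CANDIDATES if m.gene == "RYR2"}

pd.DataFrame([vars(r) for r in records]).to_csv(
    args.out / "ryr2_clinical.tsv", sep="\t", index=False
)
print(f"RYR2 carriers: n={len(records)}, QTc {round(mean)} +/- {round(sd)} ms")
print(f"events: {events['syncope']} syncope, {events['VF']} VF, "
      f"{events['CA']} cardiac arrest")
print(f"distinct RYR2 candidate mutations across both arms: "
      f"{len(family_ryr2 | unrelated_ryr2)}")
print(f"novel mutations among carriers: {sum(r.novel for r in records)}")
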