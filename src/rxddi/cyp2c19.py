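"""CYP2C19 metaboliser phenotype from star-allele diplotypes.

Citalopram is principally cleared by CYP2C19, whose common star alleles are
either no-function (*2, *3) or increased-function (*17).  Phenotype is
assigned from the unordered pair of allele functions, guideline style:

    {no_function, no_function}        → PM   (poor metaboliser)
    {no_function, normal|increased}   → IM   (intermediate)
    {normal, normal}                  → NM   (normal; analysis reference)
    {normal|increased, increased}     → RM_UM (rapid/ultrarapid, one group)

Any allele not in the function table makes the call ``indeterminate``; such
participants are excluded from CYP2C19-stratified analyses only, and retained
everywhere else.  Decreased-function alleles, if added to the table, map
conservatively to IM when paired with any known function.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

PHENOTYPES = ("PM", "IM", "NM", "RM_UM", "indeterminate")
ALLELE_FUNCTIONS = ("normal", "no_function", "increased", "decreased", "unknown")

_PAIR_TO_PHENOTYPE = {
    frozenset({"no_function"}): "PM",
    frozenset({"no_function", "normal"}): "IM",
    frozenset({"no_function", "increased"}): "IM",
    frozenset({"normal"}): "NM",
    frozenset({"normal", "increased"}): "RM_UM",
    frozenset({"increased"}): "RM_UM",
}


@dataclass(frozen=True)
class Diplotype:
    """Unordered pair of star-allele labels for one participant."""
    participant_id: str
    allele1: str
    allele2: str


def load_allele_table(path: str | Path | None = None) -> dict[str, str]:
    """Load a star-allele → function mapping (JSON object).

    Without a path, the packaged default table is used
    ({*1: normal, *2: no_function, *3: no_function, *17: increased}).
    """
    if path is None:
        path = Path(str(resources.files("rxddi").joinpath("data/cyp2c19_alleles.json")))
    table = json.loads(Path(path).read_text())
    bad = {a: f for a, f in table.items() if f not in ALLELE_FUNCTIONS}
    if bad:
        raise ValueError(f"unknown allele function(s): {bad}")
    if table.get("*1") != "normal":
        raise ValueError("allele table must map '*1' to 'normal'")
    return table


def assign_phenotype(diplotype: Diplotype, table: dict[str, str]) -> str:
    """Map one diplotype to PM/IM/NM/RM_UM or indeterminate.

    Symmetric in the two alleles.  An allele absent from the table (or mapped
    to 'unknown') yields indeterminate -- a value, not an error.
    """
    f1 = table.get(diplotype.allele1, "unknown")
    f2 = table.get(diplotype.allele2, "unknown")
    if "unknown" in (f1, f2):
        return "indeterminate"
    if "decreased" in (f1, f2):
        return "IM"
    return _PAIR_TO_PHENOTYPE[frozenset({f1, f2})]


def phenotype_series(diplotypes: pd.DataFrame, table: dict[str, str]) -> pd.Series:
    """Vectorise assign_phenotype over a diplotype table
    (columns participant_id, allele1, allele2)."""
    return pd.Series(
        [assign_phenotype(Diplotype(str(p), a1, a2), table)
         for p, a1, a2 in diplotypes[["participant_id", "allele1", "allele2"]].itertuples(index=False)],
        index=diplotypes.index, name="cyp2c19_phenotype")


def attach_phenotypes(cohort: pd.DataFrame,
                      diplotypes: pd.DataFrame,
                      table: dict[str, str] | None = None) -> pd.DataFrame:
    """Join metaboliser phenotype onto a cohort table.

    Participants with a missing diplotype or an indeterminate call get a
    missing ``cyp2c19_phenotype`` -- they drop out of phenotype-stratified
    models only (complete-case handling downstream), never from the cohort.
    """
    if table is None:
        table = load_allele_table()
    pheno = diplotypes.assign(
        cyp2c19_phenotype=phenotype_series(diplotypes, table))
    pheno.loc[pheno["cyp2c19_phenotype"] == "indeterminate",
              "cyp2c19_phenotype"] = pd.NA
    out = cohort.merge(pheno[["participant_id", "cyp2c19_phenotype"]],
                       on="participant_id", how="left")
    return out
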