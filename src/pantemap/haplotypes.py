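"""Haplotype-combination analysis over a small set of focal variants.

Accessions are partitioned by the joint presence/absence state of K
focal TE insertions (present = homozygous dosage 2, absent = dosage 0;
heterozygous or missing calls make an accession unclassifiable).
Combinations above a frequency threshold are retained and summarized
against phenotype and ecotype metadata, including how many focal
variants each accession carries.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .types import GenotypeMatrix

__all__ = ["build_combos", "combo_summary", "truncated_pct"]


def truncated_pct(count: int, total: int) -> int:
    """Integer percentage truncated toward zero (104 of 132 -> 78)."""
    if total <= 0:
        raise ParameterError("total must be positive")
    return int(100 * count // total)


def build_combos(
    gm: GenotypeMatrix,
    focal_variants: Sequence[str],
    min_freq: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Tabulate haplotype combinations of the focal variants.

    Returns ``(combos, states)``: ``combos`` is one row per observed
    combination — ``state`` (e.g. ``"+-+"``, '+' = present), per-variant
    presence columns, ``n``, ``frequency`` over classifiable accessions
    and ``retained`` (frequency strictly above ``min_freq``); ``states``
    maps each classifiable accession to its combination state string.
    """
    if not focal_variants:
        raise ParameterError("need at least one focal variant")
    if not 0.0 <= min_freq < 1.0:
        raise ParameterError("min_freq must be in [0, 1)")
    missing = [v for v in focal_variants if v not in gm.variants]
    if missing:
        raise DataError(f"focal variants not in genotype matrix: {missing}")

    d = gm.dosages.loc[list(focal_variants)]
    classifiable = d.isin([0.0, 2.0]).all(axis=0)
    d = d.loc[:, classifiable]
    n_class = int(classifiable.sum())
    if n_class == 0:
        raise DataError("no classifiable accession (all het/missing)")

    present = (d == 2.0)
    states = present.apply(
        lambda col: "".join("+" if v else "-" for v in col), axis=0)

    rows = []
    for state, group in states.groupby(states):
        n = len(group)
        row = {"state": state, "n": n, "frequency": n / n_class,
               "retained": n / n_class > min_freq}
        for v, ch in zip(focal_variants, state):
            row[v] = ch == "+"
        rows.append(row)
    combos = (pd.DataFrame(rows)
              .sort_values(["n", "state"], ascending=[False, True])
              .reset_index(drop=True))
    return combos, states


def combo_summary(
    combos: pd.DataFrame,
    states: pd.Series,
    phenotype: pd.DataFrame,
    trait: str,
    ecotype_col: str = "ecotype",
) -> dict:
    """Per-combination phenotype and ecotype composition, plus carriage.

    Returns a dict with:

    ``per_combo``
        DataFrame indexed by state: ``n``, ``frequency``, trait mean/SD
        (NaN SD for singletons), and one count column per ecotype.
    ``carriage``
        accession -> number of focal variants carried (classifiable
        accessions only).
    ``ecotype_carriage_pct``
        nested dict ``ecotype -> {m: truncated %}`` of accessions
        carrying exactly m focal variants, plus ``">=m"`` cumulative
        entries, matching the integer-truncation reporting convention.
    """
    common = states.index.intersection(phenotype.index)
    if common.empty:
        raise DataError("no overlap between combos and phenotype table")
    st = states.loc[common]
    ph = phenotype.loc[common]

    eco_levels = sorted(ph[ecotype_col].dropna().unique()) \
        if ecotype_col in ph.columns else []
    rows = []
    for _, combo in combos.iterrows():
        accs = st.index[st == combo["state"]]
        vals = ph.loc[accs, trait].dropna() if trait in ph.columns \
            else pd.Series(dtype=float)
        row = {
            "state": combo["state"],
            "n": int(combo["n"]),
            "frequency": combo["frequency"],
            "retained": combo["retained"],
            "trait_mean": float(vals.mean()) if len(vals) else float("nan"),
            "trait_sd": float(vals.std(ddof=1)) if len(vals) > 1
            else float("nan"),
        }
        for eco in eco_levels:
            row[f"n_{eco}"] = int((ph.loc[accs, ecotype_col] == eco).sum())
        rows.append(row)
    per_combo = pd.DataFrame(rows).set_index("state")

    carriage = st.map(lambda s: s.count("+"))
    eco_pct: dict[str, dict] = {}
    for eco in eco_levels:
        accs = ph.index[ph[ecotype_col] == eco]
        carr = carriage.loc[carriage.index.intersection(accs)]
        total = len(carr)
        if total == 0:
            continue
        dist = {int(m): truncated_pct(int((carr == m).sum()), total)
                for m in sorted(carr.unique())}
        cum = {f">={m}": truncated_pct(int((carr >= m).sum()), total)
               for m in sorted(carr.unique())}
        eco_pct[eco] = {"n": total, **dist, **cum}

    return {"per_combo": per_combo, "carriage": carriage,
            "ecotype_carriage_pct": eco_pct}
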