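"""Stomach-content summaries: %N, %M, %FO, IRI and prey richness.

For each prey taxon i within a predator group (taxon shares computed over
non-empty stomachs only):

    %N_i  = 100 * count_i / total count
    %M_i  = 100 * mass_i  / total mass
    %FO_i = 100 * stomachs containing i / stomachs
    IRI_i = (%N_i + %M_i) * %FO_i          (Pinkas form)
    %IRI_i = 100 * IRI_i / sum_j IRI_j

%N, %M and %IRI each sum to 100 within a group.  If a group's total prey
mass is zero while counts are positive (unweighable prey), the index
falls back to a count-only form IRI = %N * %FO, flagged in the output.

Prey richness is the number of distinct taxa per predator group; rarefied
richness resamples a common number of stomachs without replacement so
groups with unequal stomach counts are comparable.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .records import DietRecord, logger


def _diet_frame(records: Sequence[DietRecord]) -> pd.DataFrame:
    if not records:
        raise ValueError("no diet records")
    df = pd.DataFrame([{
        "predator_id": r.predator_id, "predator_species": r.predator_species,
        "area": r.area, "prey_taxon": r.prey_taxon,
        "prey_count": r.prey_count, "prey_mass_g": r.prey_mass_g,
    } for r in records])
    # one row per (stomach, taxon) after aggregation
    return (df.groupby(["predator_id", "predator_species", "area", "prey_taxon"],
                       as_index=False)
              .agg(prey_count=("prey_count", "sum"), prey_mass_g=("prey_mass_g", "sum")))


def iri_table(records: Sequence[DietRecord]) -> pd.DataFrame:
    """IRI table for one predator group (all records pooled).

    Returns one row per prey taxon with columns ``n, mass_g, pct_number,
    pct_mass, pct_fo, iri, pct_iri``, sorted by descending %IRI.
    ``result.attrs['count_only']`` is True when the count-only fallback
    was used (zero total mass).
    """
    df = _diet_frame(records)
    n_stomachs = df["predator_id"].nunique()
    by_taxon = df.groupby("prey_taxon").agg(
        n=("prey_count", "sum"),
        mass_g=("prey_mass_g", "sum"),
        stomachs=("predator_id", "nunique"),
    )
    total_n = by_taxon["n"].sum()
    total_m = by_taxon["mass_g"].sum()
    out = by_taxon.copy()
    out["pct_number"] = 100.0 * out["n"] / total_n
    out["pct_fo"] = 100.0 * out["stomachs"] / n_stomachs
    count_only = total_m == 0
    if count_only:
        logger.warning("zero total prey mass: using count-only IRI = %%N x %%FO")
        out["pct_mass"] = 0.0
        out["iri"] = out["pct_number"] * out["pct_fo"]
    else:
        out["pct_mass"] = 100.0 * out["mass_g"] / total_m
        out["iri"] = (out["pct_number"] + out["pct_mass"]) * out["pct_fo"]
    out["pct_iri"] = 100.0 * out["iri"] / out["iri"].sum()
    out = out.drop(columns="stomachs").sort_values("pct_iri", ascending=False)
    out.attrs["n_stomachs"] = int(n_stomachs)
    out.attrs["count_only"] = bool(count_only)
    return out


def iri_tables_by_group(records: Sequence[DietRecord],
                        by: tuple[str, ...] = ("predator_species", "area")
                        ) -> dict[tuple, pd.DataFrame]:
    """One IRI table per predator group (default: species x area)."""
    df = _diet_frame(records)
    out = {}
    for key, _ in df.groupby(list(by)):
        key_t = key if isinstance(key, tuple) else (key,)
        group = [r for r in records
                 if all(getattr(r, b) == k for b, k in zip(by, key_t))]
        out[key_t] = iri_table(group)
    return out


def prey_richness(records: Sequence[DietRecord],
                  by: tuple[str, ...] = ("predator_species", "area")) -> pd.DataFrame:
    """Distinct prey taxa and stomach count per predator group."""
    df = _diet_frame(records)
    return (df.groupby(list(by))
              .agg(richness=("prey_taxon", "nunique"),
                   n_stomachs=("predator_id", "nunique"))
              .reset_index())


def rarefied_richness(records: Sequence[DietRecord],
                      n_stomachs: int,
                      n_resamples: int = 1000,
                      seed: int = 0,
                      by: tuple[str, ...] = ("predator_species", "area")
                      ) -> pd.DataFrame:
    """Expected richness at a common stomach count, by resampling.

    For each group, ``n_stomachs`` stomachs are drawn without replacement
    ``n_resamples`` times (seeded); the mean number of distinct taxa is
    reported.  Groups with fewer stomachs than requested are reported at
    their observed richness with ``rarefied_at`` equal to their own size.
    At the full sample size the rarefied value equals observed richness.
    """
    df = _diet_frame(records)
    rng = np.random.default_rng(seed)
    rows = []
    for key, g in df.groupby(list(by)):
        key_t = key if isinstance(key, tuple) else (key,)
        stomach_taxa = g.groupby("predator_id")["prey_taxon"].apply(set)
        m = len(stomach_taxa)
        k = min(n_stomachs, m)
        if k == m:
            mean_rich = float(len(set().union(*stomach_taxa)))
        else:
            sets = list(stomach_taxa)
            vals = np.empty(n_resamples)
            for i in range(n_resamples):
                idx = rng.choice(m, size=k, replace=False)
                vals[i] = len(set().union(*(sets[j] for j in idx)))
            mean_rich = float(vals.mean())
        rows.append({**{b: v for b, v in zip(by, key_t)},
                     "rarefied_richness": mean_rich, "rarefied_at": k,
                     "n_stomachs": m})
    return pd.DataFrame(rows)
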