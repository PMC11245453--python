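"""Rule-driven functional/guild profiling.

Stands in for FAPROTAX-style bacterial function annotation and
FUNGuild-style fungal guild assignment: the database itself is a
user-supplied TSV of rules (match_rank, match_value, function_label,
trophic_mode) and this module only performs the aggregation.  A rule matches
a taxon when the taxon's lineage value at ``match_rank`` equals
``match_value`` (or the taxon id itself for ``match_rank == "otu"``).

With ``multi_assign=True`` (FAPROTAX semantics) a taxon's abundance is
credited in full to every matching function; with ``multi_assign=False``
(guild-style) it is split equally among the matches.  Unmatched abundance is
tracked explicitly under ``"unassigned"`` so that assigned + unassigned mass
equals the table mass per sample exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OtuTable, RANKS, relative_abundance

__all__ = ["FunctionTable", "assign_functions", "trophic_rollup"]

UNASSIGNED = "unassigned"


@dataclass
class FunctionTable:
    """Function-by-sample relative abundances plus match provenance."""

    abundance: pd.DataFrame
    provenance: dict = field(repr=False)  # taxon_id -> list of matched function labels
    multi_assign: bool = True


def _match_functions(taxon_id: str, lineage: dict, rules: pd.DataFrame) -> list:
    hits = []
    for _, rule in rules.iterrows():
        rank = rule["match_rank"]
        target = taxon_id if rank == "otu" else lineage.get(rank, "")
        if target == rule["match_value"]:
            hits.append(rule["function_label"])
    return hits


def assign_functions(
    table: OtuTable,
    taxonomy: pd.DataFrame,
    rules: pd.DataFrame,
    multi_assign: bool = True,
) -> FunctionTable:
    """Aggregate taxon relative abundances into function relative abundances."""
    if rules.empty:
        raise ValueError("rules table is empty")
    bad = set(rules["match_rank"]) - (set(RANKS) | {"otu"})
    if bad:
        raise ValueError(f"rule(s) reference unknown rank(s): {sorted(bad)}")

    rel = relative_abundance(table)
    functions = sorted(set(rules["function_label"])) + [UNASSIGNED]
    out = pd.DataFrame(0.0, index=functions, columns=table.sample_ids)
    provenance = {}
    for taxon in table.taxon_ids:
        if taxon in taxonomy.index:
            lineage = {r: taxonomy.at[taxon, r] for r in RANKS}
        else:
            lineage = {r: "" for r in RANKS}
        hits = _match_functions(taxon, lineage, rules)
        provenance[taxon] = hits
        row = rel.loc[taxon]
        if not hits:
            out.loc[UNASSIGNED] += row
        elif multi_assign:
            for f in set(hits):
                out.loc[f] += row
        else:
            share = row / len(set(hits))
            for f in set(hits):
                out.loc[f] += share
    out = out.loc[(out.sum(axis=1) > 0) | (out.index == UNASSIGNED)]
    return FunctionTable(abundance=out, provenance=provenance, multi_assign=multi_assign)


def trophic_rollup(ft: FunctionTable, rules: pd.DataFrame) -> pd.DataFrame:
    """Roll guild abundances up to trophic modes (pathotroph / symbiotroph /
    saprotroph in the fungal case) plus ``unassigned``.

    Guilds whose rules carry an empty trophic_mode, and the unassigned mass
    itself, land in ``unassigned``.  A guild mapped to several modes by
    conflicting rules contributes to each listed mode equally.
    """
    mode_by_function: dict[str, list] = {}
    for _, rule in rules.iterrows():
        modes = mode_by_function.setdefault(rule["function_label"], [])
        mode = rule["trophic_mode"] or UNASSIGNED
        if mode not in modes:
            modes.append(mode)

    modes_all = sorted({m for ms in mode_by_function.values() for m in ms} | {UNASSIGNED})
    out = pd.DataFrame(0.0, index=modes_all, columns=ft.abundance.columns)
    for func, row in ft.abundance.iterrows():
        modes = mode_by_function.get(func, [UNASSIGNED])
        for m in modes:
            out.loc[m] += row / len(modes)
    return out
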