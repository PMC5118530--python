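"""Pedigree container and structural validation.

A pedigree is held as a plain table in FAM column order (family id,
individual id, father, mother, sex) with ``"0"`` marking a missing parent and
sex coded 1 = male, 2 = female, 0 = unknown. Individual ids are globally
unique, which lets every downstream matrix be indexed by id alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import networkx as nx
import pandas as pd

from .errors import StructuralError

MISSING_PARENT = "0"
COLUMNS = ["fam", "iid", "father", "mother", "sex"]

SEX_MALE = 1
SEX_FEMALE = 2


@dataclass(frozen=True)
class Pedigree:
    """Validated set of individuals with parent links.

    Parameters
    ----------
    table:
        DataFrame with columns ``fam, iid, father, mother, sex``. String ids;
        integer sex codes (1/2/0).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        t = self.table
        missing = [c for c in COLUMNS if c not in t.columns]
        if missing:
            raise StructuralError(f"pedigree table lacks columns: {missing}")
        object.__setattr__(self, "table", t[COLUMNS].reset_index(drop=True))
        self.validate()

    # ------------------------------------------------------------------ views
    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return list(self.table["iid"])

    @property
    def families(self) -> list[str]:
        return list(pd.unique(self.table["fam"]))

    @cached_property
    def parents(self) -> dict[str, tuple[str | None, str | None]]:
        """Map iid -> (father or None, mother or None)."""
        out = {}
        for row in self.table.itertuples(index=False):
            f = None if row.father == MISSING_PARENT else row.father
            m = None if row.mother == MISSING_PARENT else row.mother
            out[row.iid] = (f, m)
        return out

    def founders(self) -> list[str]:
        return [i for i, (f, m) in self.parents.items() if f is None and m is None]

    # ------------------------------------------------------------- validation
    def validate(self) -> None:
        t = self.table
        dup = t["iid"][t["iid"].duplicated()]
        if len(dup):
            raise StructuralError(f"duplicate individual ids: {sorted(set(dup))[:5]}")
        known = set(t["iid"])
        fam_of = dict(zip(t["iid"], t["fam"]))
        sex_of = dict(zip(t["iid"], t["sex"]))
        g = nx.DiGraph()
        g.add_nodes_from(known)
        for row in t.itertuples(index=False):
            for parent, want_sex, role in (
                (row.father, SEX_MALE, "father"),
                (row.mother, SEX_FEMALE, "mother"),
            ):
                if parent == MISSING_PARENT:
                    continue
                if parent not in known:
                    raise StructuralError(
                        f"{role} {parent!r} of {row.iid!r} is not in the pedigree"
                    )
                if fam_of[parent] != row.fam:
                    raise StructuralError(
                        f"{role} {parent!r} of {row.iid!r} is in a different family"
                    )
                if sex_of[parent] not in (want_sex, 0):
                    raise StructuralError(
                        f"{role} {parent!r} of {row.iid!r} has inconsistent sex code"
                    )
                g.add_edge(parent, row.iid)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise StructuralError(f"cyclic parentage involving {cycle[0][0]!r}")

    # ---------------------------------------------------------------- helpers
    def topological_order(self) -> list[str]:
        """Individual ids ordered so every parent precedes its offspring."""
        g = nx.DiGraph()
        g.add_nodes_from(self.ids)
        for child, (f, m) in self.parents.items():
            for p in (f, m):
                if p is not None:
                    g.add_edge(p, child)
        # lexicographic tie-break keeps the order deterministic
        return list(nx.lexicographical_topological_sort(g))

    def relabelled(self, mapping: dict[str, str]) -> "Pedigree":
        """Return a copy with individual ids renamed through ``mapping``."""
        t = self.table.copy()
        t["iid"] = t["iid"].map(lambda i: mapping.get(i, i))
        for col in ("father", "mother"):
            t[col] = t[col].map(
                lambda i: i if i == MISSING_PARENT else mapping.get(i, i)
            )
        return Pedigree(t)
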