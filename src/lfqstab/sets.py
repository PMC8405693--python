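"""Gene/protein set collections (GMT-shaped) and universe restriction."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import ValidationError

__all__ = ["GeneSet", "GeneSetCollection"]


@dataclass(frozen=True)
class GeneSet:
    category_id: str
    description: str
    members: tuple


@dataclass
class GeneSetCollection:
    """An ordered collection of categories over a common identifier universe."""

    categories: list
    universe: list

    def __post_init__(self):
        ids = [c.category_id for c in self.categories]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate category ids: {dup}")

    def __len__(self):
        return len(self.categories)

    def __iter__(self):
        return iter(self.categories)

    def get(self, category_id: str) -> GeneSet:
        for c in self.categories:
            if c.category_id == category_id:
                return c
        raise KeyError(category_id)

    def restrict_to(self, universe, min_members: int = 2) -> "GeneSetCollection":
        """Intersect every category with ``universe``.

        Categories left with fewer than ``min_members`` members are dropped
        with a warning (they cannot support a set statistic).
        """
        uni = set(universe)
        kept = []
        for c in self.categories:
            members = tuple(m for m in c.members if m in uni)
            if len(members) >= min_members:
                kept.append(GeneSet(c.category_id, c.description, members))
            else:
                warnings.warn(
                    f"category {c.category_id} has {len(members)} member(s) "
                    f"after universe restriction; dropped", stacklevel=2)
        return GeneSetCollection(categories=kept, universe=list(universe))
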