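"""Multi-dimensional term taxonomy with subsumption.

A taxonomy groups named terms into disjoint *dimensions*: one dimension for
operations and ``k >= 1`` dimensions for data characterization (e.g. data
type and data format).  Subsumption is upward reachability along parent
links and is always confined to a single dimension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional

from ..errors import DimensionMismatchError, UnresolvedTermError

logger = logging.getLogger(__name__)


def iri_fragment(iri: str) -> str:
    """Short display name of an IRI: text after the last ``#`` or ``/``."""
    for sep in ("#", "/"):
        if sep in iri:
            iri = iri.rsplit(sep, 1)[1]
    return iri


@dataclass(frozen=True)
class TaxonomyTerm:
    """One named term of the taxonomy.

    ``parents`` holds the ids of the direct super-terms; it is empty exactly
    for a dimension root.  All parents live in the same dimension as the
    term itself.
    """

    id: str
    label: str
    dimension: str
    parents: FrozenSet[str] = field(default_factory=frozenset)


class DomainTaxonomy:
    """Operation dimension plus ordered data dimensions.

    Dimension ids are short names (by convention the IRI fragment of the
    dimension root).  Construction checks referential integrity and
    dimension confinement; cycle detection is deliberately left to
    :func:`wfsynth.domain_model.validate.validate_domain` so that malformed
    taxonomies can still be inspected and reported on.
    """

    def __init__(
        self,
        operation_dimension: str,
        data_dimensions: List[str],
        terms: Mapping[str, TaxonomyTerm],
        roots: Mapping[str, str],
    ) -> None:
        if not data_dimensions:
            raise ValueError("at least one data dimension is required")
        dims = [operation_dimension, *data_dimensions]
        if len(set(dims)) != len(dims):
            raise ValueError("dimension ids must be unique")
        for dim in dims:
            if dim not in roots:
                raise ValueError(f"missing root for dimension {dim!r}")
        for term in terms.values():
            if term.dimension not in dims:
                raise ValueError(
                    f"term {term.id!r} declares unknown dimension {term.dimension!r}"
                )
            for parent in term.parents:
                if parent not in terms:
                    raise ValueError(
                        f"term {term.id!r} references unknown parent {parent!r}"
                    )
                if terms[parent].dimension != term.dimension:
                    raise ValueError(
                        f"term {term.id!r} has parent {parent!r} in another dimension"
                    )
        self.operation_dimension = operation_dimension
        self.data_dimensions = list(data_dimensions)
        self.terms: Dict[str, TaxonomyTerm] = dict(terms)
        self.roots: Dict[str, str] = {d: roots[d] for d in dims}
        self._children: Dict[str, List[str]] = {tid: [] for tid in self.terms}
        for term in self.terms.values():
            for parent in term.parents:
                self._children[parent].append(term.id)
        for kids in self._children.values():
            kids.sort()
        self._desc_cache: Dict[str, FrozenSet[str]] = {}
        for dim in dims:
            if not self.is_tree(dim):
                logger.warning("dimension %r is a DAG, not a tree", dim)

    # -- basic accessors ---------------------------------------------------

    @property
    def dimensions(self) -> List[str]:
        return [self.operation_dimension, *self.data_dimensions]

    def root(self, dimension: str) -> str:
        return self.roots[dimension]

    def children(self, term_id: str) -> List[str]:
        return list(self._children[term_id])

    def terms_in(self, dimension: str) -> List[TaxonomyTerm]:
        return sorted(
            (t for t in self.terms.values() if t.dimension == dimension),
            key=lambda t: t.id,
        )

    def label(self, term_id: str) -> str:
        return self.terms[term_id].label

    def is_tree(self, dimension: str) -> bool:
        return all(
            len(t.parents) <= 1
            for t in self.terms.values()
            if t.dimension == dimension
        )

    # -- subsumption -------------------------------------------------------

    def subsumes(self, ancestor: str, descendant: str) -> bool:
        """True iff ``descendant`` equals ``ancestor`` or reaches it upward.

        Raises :class:`DimensionMismatchError` on a cross-dimension query and
        :class:`UnresolvedTermError` for unknown ids.  Terminates on cyclic
        parent links (visited-set walk).
        """
        for tid in (ancestor, descendant):
            if tid not in self.terms:
                raise UnresolvedTermError(f"unknown term {tid!r}")
        a, d = self.terms[ancestor], self.terms[descendant]
        if a.dimension != d.dimension:
            raise DimensionMismatchError(
                f"cannot compare {ancestor!r} ({a.dimension}) "
                f"with {descendant!r} ({d.dimension})"
            )
        if ancestor == descendant:
            return True
        seen = set()
        stack = [descendant]
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            for parent in self.terms[cur].parents:
                if parent == ancestor:
                    return True
                stack.append(parent)
        return False

    def descendant_closure(self, term_id: str) -> FrozenSet[str]:
        """All terms subsumed by ``term_id``, including itself."""
        cached = self._desc_cache.get(term_id)
        if cached is not None:
            return cached
        if term_id not in self.terms:
            raise UnresolvedTermError(f"unknown term {term_id!r}")
        seen = set()
        stack = [term_id]
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            stack.extend(self._children[cur])
        result = frozenset(seen)
        self._desc_cache[term_id] = result
        return result

    def closure_of(self, term_ids: Iterable[str]) -> FrozenSet[str]:
        """Union of descendant closures — the instance terms a disjunctive
        requirement accepts."""
        out: set = set()
        for tid in term_ids:
            out.update(self.descendant_closure(tid))
        return frozenset(out)

    # -- reference resolution ----------------------------------------------

    def resolve(self, ref: str, dimension: Optional[str] = None) -> str:
        """Resolve ``ref`` to a term id.

        Accepts a full id, a unique IRI fragment, or a unique label; when
        ``dimension`` is given, candidates are restricted to that dimension
        (this is how identically named terms in different dimensions are
        told apart).
        """
        pool = (
            self.terms.values()
            if dimension is None
            else (t for t in self.terms.values() if t.dimension == dimension)
        )
        pool = list(pool)
        if any(t.id == ref for t in pool):
            return ref
        matches = sorted(
            {t.id for t in pool if iri_fragment(t.id) == ref or t.label == ref}
        )
        if len(matches) == 1:
            return matches[0]
        where = f" in dimension {dimension!r}" if dimension else ""
        if not matches:
            raise UnresolvedTermError(f"unknown term reference {ref!r}{where}")
        raise UnresolvedTermError(
            f"ambiguous term reference {ref!r}{where}: {matches}"
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DomainTaxonomy):
            return NotImplemented
        return (
            self.operation_dimension == other.operation_dimension
            and self.data_dimensions == other.data_dimensions
            and self.terms == other.terms
            and self.roots == other.roots
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        sizes = {d: len(self.terms_in(d)) for d in self.dimensions}
        return f"DomainTaxonomy({sizes})"
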