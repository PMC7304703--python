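"""A small DPLL SAT solver with two-watched-literal propagation.

Written for this package because the synthesis instances are tiny (at most
a few thousand variables) and — crucially — because model enumeration must
be *canonical*: decisions follow a caller-supplied static variable order
with a fixed phase, so with chronological backtracking the first model
found is lexicographically minimal over that order, and repeated solving
under blocking clauses yields models in lexicographic order.  An
off-the-shelf CDCL solver gives no such ordering guarantee.

Literals use the DIMACS convention: variable ``v`` > 0, literal ``v`` or
``-v``.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence

from ..errors import EngineError


class SATSolver:
    def __init__(self, num_vars: int = 0) -> None:
        self.num_vars = num_vars
        self.clauses: List[List[int]] = []
        self._units: List[int] = []
        self._watches: Dict[int, List[int]] = {}
        self._unsat = False
        # assignment state (rebuilt on every solve)
        self._assign: List[int] = []
        self._trail: List[int] = []
        self._qhead = 0

    def new_var(self) -> int:
        self.num_vars += 1
        return self.num_vars

    def add_clause(self, lits: Iterable[int]) -> None:
        clause: List[int] = []
        seen = set()
        for lit in lits:
            if lit == 0 or abs(lit) > self.num_vars:
                raise EngineError(f"literal {lit} out of range")
            if -lit in seen:  # tautology
                return
            if lit not in seen:
                seen.add(lit)
                clause.append(lit)
        if not clause:
            self._unsat = True
            return
        if len(clause) == 1:
            self._units.append(clause[0])
            return
        index = len(self.clauses)
        self.clauses.append(clause)
        self._watches.setdefault(clause[0], []).append(index)
        self._watches.setdefault(clause[1], []).append(index)

    # -- internals ---------------------------------------------------------

    def _value(self, lit: int) -> int:
        value = self._assign[abs(lit)]
        return value if lit > 0 else -value

    def _enqueue(self, lit: int) -> bool:
        value = self._value(lit)
        if value == 1:
            return True
        if value == -1:
            return False
        self._assign[abs(lit)] = 1 if lit > 0 else -1
        self._trail.append(lit)
        return True

    def _propagate(self) -> bool:
        """Exhaust unit propagation; False on conflict."""
        while self._qhead < len(self._trail):
            p = self._trail[self._qhead]
            self._qhead += 1
            falsified = -p
            watching = self._watches.get(falsified, [])
            kept: List[int] = []
            pos = 0
            for pos, ci in enumerate(watching):
                clause = self.clauses[ci]
                if clause[0] == falsified:
                    clause[0], clause[1] = clause[1], clause[0]
                # now clause[1] == falsified
                if self._value(clause[0]) == 1:
                    kept.append(ci)
                    continue
                moved = False
                for k in range(2, len(clause)):
                    if self._value(clause[k]) != -1:
                        clause[1], clause[k] = clause[k], clause[1]
                        self._watches.setdefault(clause[1], []).append(ci)
                        moved = True
                        break
                if moved:
                    continue
                kept.append(ci)
                if not self._enqueue(clause[0]):  # conflict
                    kept.extend(watching[pos + 1 :])
                    self._watches[falsified] = kept
                    return False
            self._watches[falsified] = kept
        return True

    # -- public API --------------------------------------------------------

    def solve(
        self,
        decision_order: Optional[Sequence[int]] = None,
        positive_first: bool = True,
    ) -> Optional[List[bool]]:
        """Search for a model; None if unsatisfiable.

        ``decision_order`` lists variables in static decision priority;
        omitted variables are appended in ascending index order.  With
        ``positive_first`` each decision tries True before False, making
        the returned model the lexicographic maximum-first assignment over
        the decision order (i.e. canonical enumeration order).
        """
        if self._unsat:
            return None
        order = list(decision_order or [])
        present = set(order)
        order.extend(v for v in range(1, self.num_vars + 1) if v not in present)

        self._assign = [0] * (self.num_vars + 1)
        self._trail = []
        self._qhead = 0
        for lit in self._units:
            if not self._enqueue(lit):
                return None
        if not self._propagate():
            return None

        # decision stack entries: (trail length before decision, literal,
        # second phase already tried?)
        decisions: List[List[int]] = []
        cursor = 0
        while True:
            var = None
            while cursor < len(order):
                if self._assign[order[cursor]] == 0:
                    var = order[cursor]
                    break
                cursor += 1
            if var is None:
                return [False] + [self._assign[v] == 1 for v in range(1, self.num_vars + 1)]
            lit = var if positive_first else -var
            decisions.append([len(self._trail), lit, 0, cursor])
            self._enqueue(lit)
            while not self._propagate():
                # backtrack to the deepest decision with an untried phase
                while decisions and decisions[-1][2]:
                    decisions.pop()
                if not decisions:
                    return None
                mark, lit, _, cursor = decisions[-1]
                for undone in self._trail[mark:]:
                    self._assign[abs(undone)] = 0
                del self._trail[mark:]
                self._qhead = mark
                decisions[-1][1] = -lit
                decisions[-1][2] = 1
                self._enqueue(-lit)
            cursor += 1
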