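"""Derivation grammar for the secondary-structure ensemble.

Every legal secondary structure on the effective sequence corresponds to
exactly one derivation in the grammar below; that unambiguity is what lets a
single set of recursion rules serve three purposes:

* **sum-product** evaluation gives Boltzmann partition functions,
* **k-best** evaluation (min-plus over sorted candidate lists) gives the
  exact lowest-free-energy structures with deterministic tie-breaking,
* a **reverse (adjoint) pass** over the filled tables converts partition
  function ratios into base-pair probabilities — the backtracking step: the
  root starts at probability 1.0 and outside weights are propagated down
  through every recursion term.

Node kinds
----------
``("B", i, j)``
    all conformations of ``[i, j]`` with ``(i, j)`` paired (the pair is
    *emitted* here; its closing loop is chosen among hairpin, stack,
    bulge/internal, or multiloop).
``("F", x, y, prev, m, ctx, closing, lstate)``
    a left-to-right scan filling ``[x, y]`` with zero or more helix branches.
    ``prev`` remembers the pair and distance of the nearest helix end to the
    left (only distances 1 and 2 matter — they are the coaxial-stacking
    window), ``m`` is the minimum number of branches still required, ``ctx``
    distinguishes exterior scans from physical multiloops (``mln``) and
    linker-containing, energy-free multiloops (``mll``), ``closing`` carries
    the closing pair for end-of-loop coaxial terms, and ``lstate`` enforces
    that a physical multiloop spanning the phantom linker has the linker
    buried inside one of its branches.

All indices here are 0-based.
"""

from __future__ import annotations

import sys
from collections import defaultdict

from .energy_model import INF, EnergyModel, coaxial_free_energy, stack_free_energy
from .errors import StateError, ValidationError
from .sequence import EffectiveSequence


class Engine:
    """Grammar evaluator bound to one (sequence, model, constraints) triple."""

    def __init__(
        self,
        seq: EffectiveSequence,
        model: EnergyModel,
        allowed=None,
        forced_unpaired=(),
        region=None,
    ):
        self.seq = seq
        self.model = model
        self.allowed = allowed  # 0-based predicate or None
        self.forced = frozenset(forced_unpaired)
        self.region = region if region is not None else (0, seq.n - 1)
        self._value = {}
        self._terms_cache = {}
        lo, hi = self.region
        self._candidates = {}
        for i in range(lo, hi + 1):
            self._candidates[i] = [j for j in range(i + 1, hi + 1) if self.pairable(i, j)]

    # -- conformational rules -------------------------------------------------

    def pairable(self, i: int, j: int) -> bool:
        lo, hi = self.region
        if not (lo <= i < j <= hi):
            return False
        if i in self.forced or j in self.forced:
            return False
        if not self.seq.can_pair(i, j):
            return False
        if self.allowed is not None and not self.allowed(i, j):
            return False
        return True

    @property
    def root(self):
        lo, hi = self.region
        return ("F", lo, hi, None, 0, "ext", None, "na")

    # -- term enumeration -----------------------------------------------------

    def terms(self, node):
        """Yield ``(dG contribution, children)`` for each recursion term."""
        cached = self._terms_cache.get(node)
        if cached is None:
            cached = list(self._gen_terms(node))
            self._terms_cache[node] = cached
        return cached

    def _gen_terms(self, node):
        seq, model = self.seq, self.model
        s = seq.bases
        if node[0] == "F":
            _, x, y, prev, m, ctx, closing, lstate = node
            if x > y:
                if m == 0 and lstate != "need":
                    dg = 0.0
                    if closing is not None and prev is not None:
                        dg = coaxial_free_energy(model, prev[1], closing, prev[0] - 1)
                    yield (dg, ())
                return
            a_ml, b_ml, c_ml = model.multiloop_params
            # leave x unpaired
            linker_here = seq.is_linker(x)
            if not (ctx == "mln" and lstate == "need" and linker_here):
                dg = c_ml if ctx == "mln" else 0.0
                nxt = None if (prev is None or prev[0] >= 2) else (2, prev[1])
                yield (dg, (("F", x + 1, y, nxt, m, ctx, closing, lstate),))
            # or start a branch (x, l)
            for l in self._candidates[x]:
                if l > y:
                    break
                spans = seq.linker_in(x + 1, l - 1)
                if ctx == "mll" and spans:
                    continue  # the linker must stay unpaired in this loop
                nxt_lstate = "na" if (lstate == "need" and spans) else lstate
                dg = b_ml if ctx == "mln" else 0.0
                if prev is not None:
                    dg += coaxial_free_energy(model, prev[1], (s[x], s[l]), prev[0] - 1)
                yield (
                    dg,
                    (
                        ("B", x, l),
                        ("F", l + 1, y, (1, (s[l], s[x])), max(m - 1, 0),
                         ctx, closing, nxt_lstate),
                    ),
                )
        else:  # ("B", i, j)
            _, i, j = node
            # hairpin closure
            if seq.linker_in(i + 1, j - 1):
                yield (0.0, ())
            else:
                yield (self._hairpin_dg(j - i - 1), ())
            # single interior branch: stack, bulge or internal loop
            for k in range(i + 1, j):
                for l in self._candidates.get(k, ()):
                    if l > j - 1:
                        break
                    yield (self._two_loop_dg(i, j, k, l), (("B", k, l),))
            # multiloop: two or more interior branches
            if j - i - 1 >= 2:
                closing = (s[j], s[i])
                prev0 = (1, (s[i], s[j]))
                a_ml, b_ml, _ = model.multiloop_params
                if seq.linker_in(i + 1, j - 1):
                    yield (a_ml + b_ml,
                           (("F", i + 1, j - 1, prev0, 2, "mln", closing, "need"),))
                    yield (0.0,
                           (("F", i + 1, j - 1, prev0, 2, "mll", closing, "na"),))
                else:
                    yield (a_ml + b_ml,
                           (("F", i + 1, j - 1, prev0, 2, "mln", closing, "na"),))

    def _hairpin_dg(self, length: int) -> float:
        from .energy_model import _length_indexed

        return _length_indexed(self.model.hairpin_init, length, self.model.rt,
                               self.model.long_loop_extension)

    def _two_loop_dg(self, i, j, k, l) -> float:
        seq, model, s = self.seq, self.model, self.seq.bases
        if k == i + 1 and l == j - 1:
            return stack_free_energy(model, (s[i], s[j]), (s[k], s[l]))
        s1, s2 = k - i - 1, j - l - 1
        if seq.linker_in(i + 1, k - 1) or seq.linker_in(l + 1, j - 1):
            return 0.0
        from .energy_model import _length_indexed

        if s1 == 0 or s2 == 0:
            return _length_indexed(model.bulge_init, s1 + s2, model.rt,
                                   model.long_loop_extension)
        init = _length_indexed(model.internal_init, s1 + s2, model.rt,
                               model.long_loop_extension)
        asym = min(model.internal_asym_max,
                   model.internal_asym_coef * abs(s1 - s2))
        return init + asym

    # -- sum-product ----------------------------------------------------------

    def value(self, node=None) -> float:
        """Boltzmann-weighted sum over all derivations of ``node``."""
        if node is None:
            node = self.root
        memo = self._value
        if node in memo:
            return memo[node]
        limit = sys.getrecursionlimit()
        need = 4 * (self.region[1] - self.region[0] + 10) + 100
        if limit < need:
            sys.setrecursionlimit(need)
        return self._value_rec(node)

    def _value_rec(self, node) -> float:
        memo = self._value
        got = memo.get(node)
        if got is not None:
            return got
        total = 0.0
        for dg, children in self.terms(node):
            w = self.model.boltzmann(dg)
            if w == 0.0:
                continue
            for c in children:
                w *= self._value_rec(c)
                if w == 0.0:
                    break
            total += w
        memo[node] = total
        return total

    def z_total(self) -> float:
        return self.value(self.root)

    # -- backtracking (outside / adjoint pass) --------------------------------

    @staticmethod
    def _span(node):
        if node[0] == "F":
            return node[2] - node[1]
        return node[2] - node[1]

    def pair_probabilities(self) -> dict:
        """Probability of every pair, by backtracking from the root.

        The root's outside weight is initialised to 1.0 and pushed down
        through each recursion term; the probability of pair ``(i, j)`` is
        the outside weight of node ``("B", i, j)`` times its inside value,
        normalised by the total partition function.
        """
        z = self.z_total()
        if z <= 0.0:
            raise StateError("total partition function is zero; nothing to backtrack")
        adj = defaultdict(float)
        adj[self.root] = 1.0
        # Parents strictly precede children when sorted by decreasing span
        # with F nodes ahead of B nodes at equal span.
        order = sorted(self._value, key=lambda n: (-self._span(n), n[0] != "F"))
        for node in order:
            a = adj.get(node, 0.0)
            if a == 0.0:
                continue
            for dg, children in self.terms(node):
                w = self.model.boltzmann(dg)
                if w == 0.0 or not children:
                    continue
                vals = [self._value[c] for c in children]
                for idx, c in enumerate(children):
                    contrib = a * w
                    for k, v in enumerate(vals):
                        if k != idx:
                            contrib *= v
                    if contrib:
                        adj[c] += contrib
        probs = {}
        for node, v in self._value.items():
            if node[0] == "B" and v > 0.0:
                p = adj.get(node, 0.0) * v / z
                if p > 0.0:
                    probs[(node[1], node[2])] = min(p, 1.0)
        return probs

    # -- exact k-best ---------------------------------------------------------

    def kbest(self, k: int):
        """The ``k`` lowest-free-energy structures as ``(dG, pairs)`` tuples.

        Tuples are ordered by free energy, ties broken lexicographically on
        the sorted pair list; ``pairs`` are 0-based.  Exact because the
        grammar is unambiguous: every structure appears exactly once.
        """
        if k < 1:
            raise ValidationError("k must be at least 1")
        memo = {}

        limit = sys.getrecursionlimit()
        need = 4 * (self.region[1] - self.region[0] + 10) + 100
        if limit < need:
            sys.setrecursionlimit(need)

        def best(node):
            got = memo.get(node)
            if got is not None:
                return got
            cands = []
            for dg, children in self.terms(node):
                if dg == INF:
                    continue
                if not children:
                    cands.append((dg, ()))
                    continue
                lists = [best(c) for c in children]
                if any(not l for l in lists):
                    continue
                if len(lists) == 1:
                    for d1, p1 in lists[0]:
                        cands.append((dg + d1, p1))
                else:
                    for d1, p1 in lists[0]:
                        for d2, p2 in lists[1]:
                            cands.append((dg + d1 + d2, tuple(sorted(p1 + p2))))
            if node[0] == "B":
                ij = (node[1], node[2])
                cands = [(d, tuple(sorted(p + (ij,)))) for d, p in cands]
            cands.sort()
            result = cands[:k]
            memo[node] = result
            return result

        return best(self.root)
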