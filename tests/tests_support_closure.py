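"""Independent told-subsumption oracle used by module soundness tests.

Deliberately separate from onehealthnlp.ontology.SubsumptionIndex: a
plain edge-collection plus iterated-set closure, so that module
extraction is checked against an implementation it does not share code
with.
"""

from onehealthnlp.ontology import And, EquivalentTo, Named, SubClassOf


def _named(expr):
    if isinstance(expr, Named):
        return [expr.id]
    if isinstance(expr, And):
        return [n for c in expr.conjuncts for n in _named(c)]
    return []


def told_closure(ontology):
    """node -> reflexively/transitively reachable told superclasses."""
    edges = set()
    nodes = set(ontology.signature().class_ids)
    for ax in ontology:
        if isinstance(ax, SubClassOf) and isinstance(ax.lhs, Named):
            for sup in _named(ax.rhs):
                edges.add((ax.lhs.id, sup))
        elif isinstance(ax, EquivalentTo):
            if isinstance(ax.lhs, Named) and isinstance(ax.rhs, Named):
                edges.add((ax.lhs.id, ax.rhs.id))
                edges.add((ax.rhs.id, ax.lhs.id))
            elif isinstance(ax.lhs, Named):
                for sup in _named(ax.rhs):
                    edges.add((ax.lhs.id, sup))
            elif isinstance(ax.rhs, Named):
                for sup in _named(ax.lhs):
                    edges.add((ax.rhs.id, sup))
    reach = {n: {n} for n in nodes}
    for a, b in edges:
        reach.setdefault(a, {a}).add(b)
        reach.setdefault(b, {b})
    changed = True
    while changed:
        changed = False
        for a in reach:
            new = set()
            for b in reach[a]:
                new |= reach.get(b, {b})
            if not new <= reach[a]:
                reach[a] |= new
                changed = True
    return reach
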