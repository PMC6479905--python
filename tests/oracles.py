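"""Independent brute-force oracles used by the test suite.

Each oracle deliberately avoids the package's own data structures and
algorithms: route enumeration is a hand-rolled recursive depth-first
search over (substrate, product, role) triples; capability calls are
re-derived from those paths by direct presence checks; the chi-square
statistic is the textbook double loop; dereplication is a plain
union-find; the taxonomy LCA is an upward walk on an explicit tree.
"""

from __future__ import annotations

from itertools import combinations


def dfs_role_paths(roles, start: str, goal: str) -> set[tuple[str, ...]]:
    """All simple role-paths start->goal; roles are (role_id, substrate, product)."""
    edges: dict[str, list[tuple[str, str]]] = {}
    for role_id, sub, prod in roles:
        edges.setdefault(sub, []).append((role_id, prod))
    out: set[tuple[str, ...]] = set()

    def walk(node, visited, path):
        if node == goal:
            out.add(tuple(path))
            return
        for role_id, nxt in edges.get(node, []):
            if nxt not in visited:
                walk(nxt, visited | {nxt}, path + [role_id])

    walk(start, {start}, [])
    return out


def oracle_capabilities(catalog, ko_set):
    """Re-derive (trp_products, denovo, per-intermediate routes) by brute force."""
    roles = [(r.role_id, r.substrate, r.product) for r in catalog.roles.values()]
    present = {
        r.role_id for r in catalog.roles.values() if set(ko_set) & set(r.ko_ids)
    }
    trp_products = {
        (r.role_id, r.product)
        for r in catalog.roles.values()
        if r.substrate == catalog.source and r.role_id in present
    }
    denovo = set()
    for path in dfs_role_paths(roles, catalog.source, catalog.terminal):
        if all(step in present for step in path):
            first = catalog.roles[path[0]].product
            denovo.add(catalog.pathway_of(first))
    intermediate_paths = {}
    for met in catalog.intermediate_ids:
        covered = {
            path
            for path in dfs_role_paths(roles, met, catalog.terminal)
            if all(step in present for step in path)
        }
        intermediate_paths[met] = covered
    partial = {
        catalog.pathway_of(met)
        for met, covered in intermediate_paths.items()
        if covered and catalog.pathway_of(met) not in denovo
    }
    return trp_products, denovo, intermediate_paths, partial


def chi_square_direct(table):
    """Textbook sum((O-E)^2 / E) with expected counts from the margins."""
    rows = len(table)
    cols = len(table[0])
    row_sums = [sum(table[i]) for i in range(rows)]
    col_sums = [sum(table[i][j] for i in range(rows)) for j in range(cols)]
    total = sum(row_sums)
    stat = 0.0
    for i in range(rows):
        for j in range(cols):
            expected = row_sums[i] * col_sums[j] / total
            stat += (table[i][j] - expected) ** 2 / expected
    dof = (rows - 1) * (cols - 1)
    return stat, dof


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def clusters(self):
        groups: dict[str, set] = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return {frozenset(g) for g in groups.values()}


def exhaustive_rarefaction_mean(signatures, depth):
    """Average distinct-signature count over all C(n, depth) subsets."""
    n = len(signatures)
    total = 0
    count = 0
    for subset in combinations(range(n), depth):
        total += len({signatures[i] for i in subset})
        count += 1
    return total / count


def tree_lca_depth_walk(lineages):
    """Deepest common ancestor of full lineages via an explicit tree walk.

    Builds the taxonomy tree rooted at an artificial node, locates each
    lineage's tip, and walks ancestor sets upward.
    """
    if not lineages:
        return ()
    paths = [tuple(l) for l in lineages]
    ancestor_sets = []
    for path in paths:
        ancestors = {path[:i] for i in range(len(path) + 1)}
        ancestor_sets.append(ancestors)
    common = set.intersection(*ancestor_sets)
    return max(common, key=len)
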