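"""Greedy dense module search (DMS).

Every node of the weighted network is used once as a seed.  From the current
module, the candidate pool is the neighborhood within hop distance d
(default 2) of the whole module, recomputed after every accepted addition.
The candidate whose addition gives the highest new score Z_{m+1} is added iff

    Z_{m+1} > Z_m * (1 + r)

with expansion rate r = 0.1 by default; the search stops when the best
candidate fails this test.  Because Z_{m+1} = (z_sum + z_c)/sqrt(k+1) is
increasing in the candidate weight z_c, the best candidate is simply the
highest-weight gene in the pool; ties are broken by the lexicographically
smallest symbol so results are deterministic across runs and platforms.

The acceptance inequality is applied literally even when Z_m < 0, where
multiplying by (1 + r) lowers the bar; with negative scores modules can
therefore still grow as long as each step clears the relaxed threshold.

A candidate at distance 2 need not share an edge with any current member, so
member sets are dense in score but not guaranteed edge-connected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DomainError
from .network import WeightedNetwork

DEFAULT_R = 0.1
DEFAULT_D = 2


@dataclass(frozen=True)
class Step:
    gene: str
    score_before: float
    score_after: float


@dataclass
class Module:
    seed: str
    members: list[str]
    zm: float
    trace: list[Step] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.members)


def grow_module(
    net: WeightedNetwork, seed: str, r: float = DEFAULT_R, d: int = DEFAULT_D
) -> Module:
    """Grow the best-scoring module from one seed gene."""
    if r <= -1:
        raise DomainError(f"expansion rate r must exceed -1, got {r}")
    if d < 1:
        raise DomainError(f"hop distance d must be >= 1, got {d}")
    i0 = net._idx(seed)
    members = [i0]
    member_set = {i0}
    z_sum = float(net.z[i0])
    zm = z_sum
    trace: list[Step] = []
    candidates = set(net.hop_ball(i0, d))
    candidates -= member_set
    while candidates:
        # best candidate: max z, ties by smallest symbol
        best = None
        best_z = -math.inf
        for c in candidates:
            zc = net.z[c]
            if zc > best_z or (zc == best_z and net.nodes[c] < net.nodes[best]):
                best, best_z = c, zc
        new_score = (z_sum + best_z) / math.sqrt(len(members) + 1)
        if not new_score > zm * (1 + r):
            break
        trace.append(Step(net.nodes[best], zm, new_score))
        members.append(best)
        member_set.add(best)
        z_sum += best_z
        zm = new_score
        candidates |= net.hop_ball(best, d)
        candidates -= member_set
    return Module(
        seed=seed,
        members=[net.nodes[i] for i in members],
        zm=zm,
        trace=trace,
    )


def search_all(
    net: WeightedNetwork, r: float = DEFAULT_R, d: int = DEFAULT_D
) -> list[Module]:
    """Run the greedy search from every node; one module per seed.

    Seeds are processed independently (results do not depend on order);
    output is sorted by seed symbol.  Distinct seeds may converge on the
    same member set; duplicates are retained.
    """
    return [grow_module(net, seed, r=r, d=d) for seed in net.nodes]


def modules_to_frame(modules: list[Module]):
    """Module table: seed, members (semicolon-joined), k, Zm."""
    import pandas as pd

    return pd.DataFrame(
        {
            "seed": [m.seed for m in modules],
            "members": [";".join(m.members) for m in modules],
            "k": [m.k for m in modules],
            "zm": [m.zm for m in modules],
        }
    )
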