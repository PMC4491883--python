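"""Boolean-network semantics for a signed pathway diagram.

Each node becomes a logic rule over its regulators: the sources of incoming
activating edges are its activators, the sources of incoming inhibiting edges
its inhibitors. Updates are synchronous and inhibitor-dominant:

* activators present:        next(v) = OR(activators) AND NOT OR(inhibitors)
* only inhibitors present:   next(v) = NOT OR(inhibitors)
* no regulators:             next(v) = v   (inputs hold their state)

Experimental perturbations clamp nodes: an enhansive perturbation forces a
node ON, a repressive one forces it OFF, before every readout.

With n nodes the synchronous dynamics is a function on 2^n states, so every
trajectory eventually enters a cycle; :func:`attractors` enumerates all
cycles exhaustively for n <= 20.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .diagram import ACTIVATE, INHIBIT, Diagram
from .errors import CapabilityError, ContractError
from .linking import ENHANSIVE, LinkMap

State = dict[str, int]


@dataclass
class BooleanRule:
    node_id: str
    activators: set[str] = field(default_factory=set)
    inhibitors: set[str] = field(default_factory=set)


@dataclass
class StateTrajectory:
    states: list[State]
    clamps: dict[str, int] = field(default_factory=dict)


def derive_rules(diagram: Diagram) -> dict[str, BooleanRule]:
    """One rule per node from the incoming signed edges."""
    rules = {n.id: BooleanRule(n.id) for n in diagram.nodes}
    for e in diagram.edges:
        if e.sense == ACTIVATE:
            rules[e.target].activators.add(e.source)
        elif e.sense == INHIBIT:
            rules[e.target].inhibitors.add(e.source)
    return rules


def clamps_from_links(linkmap: LinkMap, condition: str | None = None) -> dict[str, int]:
    """Clamp map from perturbation links: enhansive -> 1, repressive -> 0.

    With ``condition`` given, only that condition's links apply.
    """
    clamps: dict[str, int] = {}
    for p in linkmap.perturbation_links:
        if condition is not None and p.condition != condition:
            continue
        clamps[p.node_id] = 1 if p.effect == ENHANSIVE else 0
    return clamps


def _apply_clamps(state: State, clamps: dict[str, int]) -> State:
    if not clamps:
        return state
    out = dict(state)
    out.update(clamps)
    return out


def step(state: State, rules: dict[str, BooleanRule],
         clamps: dict[str, int] | None = None) -> State:
    """One synchronous update; clamped nodes are forced in the result."""
    clamps = clamps or {}
    if set(state) != set(rules):
        raise ContractError("state must cover exactly the rule nodes")
    nxt: State = {}
    for nid, rule in rules.items():
        if not rule.activators and not rule.inhibitors:
            nxt[nid] = state[nid]
            continue
        inhibited = any(state[i] for i in rule.inhibitors)
        if rule.activators:
            nxt[nid] = int(any(state[a] for a in rule.activators) and not inhibited)
        else:
            nxt[nid] = int(not inhibited)
    return _apply_clamps(nxt, clamps)


def simulate(rules: dict[str, BooleanRule], init: State, T: int,
             clamps: dict[str, int] | None = None) -> StateTrajectory:
    """Trajectory of T synchronous steps (T+1 states incl. the clamped init)."""
    clamps = clamps or {}
    state = _apply_clamps(dict(init), clamps)
    states = [state]
    for _ in range(T):
        state = step(state, rules, clamps)
        states.append(state)
    return StateTrajectory(states=states, clamps=dict(clamps))


def _encode(state: State, order: list[str]) -> int:
    code = 0
    for i, nid in enumerate(order):
        code |= state[nid] << i
    return code


def _decode(code: int, order: list[str]) -> State:
    return {nid: (code >> i) & 1 for i, nid in enumerate(order)}


def attractors(rules: dict[str, BooleanRule],
               clamps: dict[str, int] | None = None) -> list[list[State]]:
    """All cycles of the synchronous state-transition graph, by exhaustive
    enumeration of the 2^n states. Limited to n <= 20.

    Each attractor is returned as the list of states along one traversal of
    the cycle, starting from its smallest encoded state; attractors are
    sorted by that representative for determinism.
    """
    order = sorted(rules)
    n = len(order)
    if n > 20:
        raise CapabilityError(
            f"exhaustive attractor search limited to 20 nodes, got {n}; "
            "sample trajectories with simulate() instead")
    clamps = clamps or {}
    succ: list[int] = []
    for code in range(1 << n):
        state = _apply_clamps(_decode(code, order), clamps)
        succ.append(_encode(step(state, rules, clamps), order))

    seen = [0] * (1 << n)  # 0 unvisited, 1 in progress, 2 done
    cycles: list[list[int]] = []
    for start in range(1 << n):
        if seen[start]:
            continue
        path, code = [], start
        index = {}
        while seen[code] == 0:
            seen[code] = 1
            index[code] = len(path)
            path.append(code)
            code = succ[code]
        if seen[code] == 1:  # new cycle discovered within this walk
            cycles.append(path[index[code]:])
        for c in path:
            seen[c] = 2

    out = []
    for cyc in sorted(cycles, key=min):
        k = cyc.index(min(cyc))
        rotated = cyc[k:] + cyc[:k]
        out.append([_decode(c, order) for c in rotated])
    return out


def cycle_length(traj: StateTrajectory) -> int | None:
    """Period of the cycle a trajectory has entered, or None if not yet
    revisiting any state."""
    order = sorted(traj.states[0])
    codes = [_encode(s, order) for s in traj.states]
    seen: dict[int, int] = {}
    for i, c in enumerate(codes):
        if c in seen:
            return i - seen[c]
        seen[c] = i
    return None
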