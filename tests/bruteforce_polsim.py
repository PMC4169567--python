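"""Independent brute-force reference for the pausing model.

A deliberately naive re-implementation used only as a test oracle: each
polymerase is an explicit object, occupancy is a position->polymerase dict,
and every initiation/stall/termination/completion is appended to an event
log.  Shares only the model's stated rules with the package implementation,
none of its code.
"""

from dataclasses import dataclass, field


@dataclass
class _Pol:
    pos: int
    wait: int


@dataclass
class EventLog:
    events: list = field(default_factory=list)  # (t, kind, length)

    def count(self, kind, t_min=0):
        return sum(1 for t, k, _ in self.events if k == kind and t >= t_min)

    def lengths(self, kind, t_min=0):
        return [l for t, k, l in self.events if k == kind and t >= t_min]


def brute_force(L, dtau, pauses, T, v=1):
    """Step-by-step simulation with an explicit event log.

    Rules: one new polymerase every ``dtau`` units at position 1 (blocked if
    occupied); ``v`` bp per unit; a pause position holds a polymerase for
    its stall time; a polymerase whose next base carries a stalled
    polymerase releases its transcript immediately.  Polymerases are
    updated from the most 3' to the most 5' within each step.
    """
    dwell = {pos: max(1, dt) for pos, dt in pauses}
    occupied: dict[int, _Pol] = {}
    log = EventLog()
    pols: list[_Pol] = []  # ordered oldest (most 3') first
    for t in range(T):
        survivors = []
        for pol in pols:  # oldest first = most 3' first
            if pol.wait > 0:
                pol.wait -= 1
                survivors.append(pol)
                continue
            del occupied[pol.pos]
            done = None
            for _ in range(v):
                nxt = pol.pos + 1
                if nxt in occupied:
                    done = ("truncated", pol.pos)
                    break
                if nxt > L:
                    done = ("full", L)
                    break
                pol.pos = nxt
                if dwell.get(nxt, 1) > 1:
                    break
            if done is not None:
                log.events.append((t, done[0], done[1]))
            else:
                pol.wait = dwell.get(pol.pos, 1) - 1
                occupied[pol.pos] = pol
                survivors.append(pol)
        pols = survivors
        if t % dtau == 0:
            log.events.append((t, "initiation", 0))
            if 1 in occupied:
                log.events.append((t, "blocked", 0))
            else:
                pol = _Pol(pos=1, wait=dwell.get(1, 1) - 1)
                occupied[1] = pol
                pols.append(pol)
    return log, pols
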