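"""Demographic scenarios: rooted histories of population splits.

A scenario is the unit the ABC machinery compares: an ordered list of
populations, per-population effective sizes, and split events ``(time,
derived, source)`` meaning that, looking backward in time, the derived
population merges into its source ``time`` generations ago.  No migration is
modeled between splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import msprime


class ScenarioError(ValueError):
    pass


@dataclass
class Scenario:
    """A rooted invasion history for coalescent simulation.

    ``events`` must form a tree over ``populations``: every population except
    one root has exactly one origin, and a source must not itself have split
    off earlier (forward in time) than its derived population.
    """

    name: str
    populations: list[str]
    events: list[tuple[float, str, str]]  # (time_generations, derived, source)

    def __post_init__(self) -> None:
        pops = set(self.populations)
        derived_seen: dict[str, float] = {}
        for t, derived, source in self.events:
            if t <= 0:
                raise ScenarioError(f"non-positive event time {t}")
            if derived not in pops or source not in pops:
                raise ScenarioError(f"event references unknown population {derived}/{source}")
            if derived in derived_seen:
                raise ScenarioError(f"population {derived} has two origins")
            derived_seen[derived] = t
        roots = pops - set(derived_seen)
        if len(roots) != 1:
            raise ScenarioError(f"scenario must have exactly one root, got {sorted(roots)}")
        # each derived population must merge into a source that still exists
        # at that time (source's own split, if any, is older)
        for t, derived, source in self.events:
            if source in derived_seen and derived_seen[source] < t:
                raise ScenarioError(
                    f"{derived} merges into {source} at {t} but {source} "
                    f"split off more recently ({derived_seen[source]})"
                )

    @property
    def root(self) -> str:
        derived = {d for _, d, _ in self.events}
        return next(p for p in self.populations if p not in derived)

    def demography(self, ne: dict[str, float]) -> msprime.Demography:
        """msprime demography with mass migrations implementing the splits."""
        dem = msprime.Demography()
        for pop in self.populations:
            dem.add_population(name=pop, initial_size=ne[pop])
        for t, derived, source in sorted(self.events):
            dem.add_mass_migration(time=t, source=derived, dest=source, proportion=1.0)
        dem.sort_events()
        return dem


def single_population(name: str = "P0") -> Scenario:
    return Scenario(name="single", populations=[name], events=[])


# The six invasion histories analysed in the study: four global scenarios
# contrasting candidate native regions, and two Baltic scenarios contrasting
# a southern (North Sea) entry with a Ponto-Caspian entry into the north.
# Population codes: AR Argentina, PU Pacific US, FR France, JP Japan,
# BL Black Sea, CS Caspian Sea, BA_S/BA_N southern/northern Baltic.

GLOBAL_POPULATIONS = ["AR", "PU", "FR", "JP", "BL", "CS", "BA_S", "BA_N"]

#: population groupings used for the Baltic scenarios
BALTIC_SOUTH = ["Kiel", "Torhamn", "Estonia"]
BALTIC_NORTH = ["Oregrund", "Umea"]


def global_scenarios(t: dict[str, float] | None = None) -> list[Scenario]:
    """The four global invasion scenarios (native region alternatives).

    ``t`` optionally maps event ranks ``e1 < e2 < ...`` (oldest first) to
    times in generations; defaults are equally spaced placeholders that
    prior sampling overrides.
    """
    t = t or {f"e{i}": 1000.0 * (7 - i) for i in range(1, 8)}
    s1 = Scenario(  # Atlantic Americas native; one branch Pacific/Asia, one Europe
        name="global-1-atlantic-native",
        populations=GLOBAL_POPULATIONS,
        events=[
            (t["e1"], "PU", "AR"), (t["e2"], "JP", "PU"), (t["e3"], "BL", "JP"),
            (t["e4"], "CS", "BL"), (t["e2"], "FR", "AR"), (t["e5"], "BA_S", "FR"),
            (t["e6"], "BA_N", "BA_S"),
        ],
    )
    s2 = Scenario(  # Pacific native; Asia direct, Atlantic then Europe
        name="global-2-pacific-native",
        populations=GLOBAL_POPULATIONS,
        events=[
            (t["e1"], "JP", "PU"), (t["e2"], "BL", "JP"), (t["e3"], "CS", "BL"),
            (t["e1"], "AR", "PU"), (t["e2"], "FR", "AR"), (t["e4"], "BA_S", "FR"),
            (t["e5"], "BA_N", "BA_S"),
        ],
    )
    s3 = Scenario(  # Argentina native, early Europe, Baltic then Ponto-Caspian
        name="global-3-early-europe",
        populations=GLOBAL_POPULATIONS,
        events=[
            (t["e1"], "FR", "AR"), (t["e2"], "BA_S", "FR"), (t["e3"], "BA_N", "BA_S"),
            (t["e4"], "BL", "BA_S"), (t["e5"], "CS", "BL"), (t["e2"], "PU", "AR"),
            (t["e3"], "JP", "PU"),
        ],
    )
    s4 = Scenario(  # Europe native
        name="global-4-europe-native",
        populations=GLOBAL_POPULATIONS,
        events=[
            (t["e1"], "AR", "FR"), (t["e2"], "PU", "AR"), (t["e3"], "JP", "PU"),
            (t["e2"], "BL", "FR"), (t["e4"], "CS", "BL"), (t["e5"], "BA_S", "FR"),
            (t["e6"], "BA_N", "BA_S"),
        ],
    )
    return [s1, s2, s3, s4]


def baltic_scenarios(t_old: float = 2000.0, t_young: float = 500.0) -> list[Scenario]:
    """Two Baltic invasion scenarios: south-to-north vs Ponto-Caspian north."""
    pops = ["FR", "BL", "BA_S", "BA_N"]
    south_first = Scenario(
        name="baltic-1-south-to-north",
        populations=pops,
        events=[
            (t_old, "BL", "FR"),
            (t_old, "BA_S", "FR"),
            (t_young, "BA_N", "BA_S"),
        ],
    )
    ponto_caspian = Scenario(
        name="baltic-2-ponto-caspian-north",
        populations=pops,
        events=[
            (t_old, "BL", "FR"),
            (t_old, "BA_S", "FR"),
            (t_young, "BA_N", "BL"),
        ],
    )
    return [south_first, ponto_caspian]
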