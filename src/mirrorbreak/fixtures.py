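"""Bundled mechanism files for the worked homochirality models.

Every fixture is stored as a plain-text model file in the package's
restricted key/value dialect and parsed on demand, so the bundled texts
double as format examples.  Only mechanisms whose reaction lists are fully
known are bundled; :func:`load_model_file` accepts user files in the same
format for anything else.
"""

from __future__ import annotations

from .network_model import ReactionNetwork, parse_model

__all__ = ["list_fixtures", "load_fixture", "load_model_file", "fixture_text"]


_KONDEPUDI_NELSON = """\
modelname = 'Kondepudi-Nelson'
species = ['L', 'D']
# Reversible lines are shipped pre-expanded so reaction indices match the
# interleaved L/D numbering used throughout the analyses (0..8).
reactions = [
    "      ->   L",   # 0
    "      ->   D",   # 1
    "L     ->    ",   # 2
    "D     ->    ",   # 3
    "L     -> 2 L",   # 4
    "D     -> 2 D",   # 5
    "2 L   ->   L",   # 6
    "2 D   ->   D",   # 7
    "L + D ->    ",   # 8
]
analyses = {
    "trace-determinant": {"enabled": True, "2by2-jacobian": True, "num-samples": 10},
    "sna": {"enabled": True, "dual-pairs-in-ec": False,
            "instability-heuristic": "mineurs", "sum-mineurs": True,
            "max-mineur-search-stop": 5, "simplification-tries": 10000,
            "num-samples": 10},
    "six-categories": {"enabled": True, "num-samples": 10},
    "frank-ineq-nonlinear": {"enabled": True},
    "frank-ineq-linear": {"enabled": True, "dual-pairs-in-ec": True,
                          "num-samples": 10, "samples-for-proportion": 100},
    "frank-pseudoquiral": {"enabled": True, "enantiomeric-pairs": [(0, 1)],
                           "dual-pairs-in-ec": True,
                           "instability-heuristic": "mineurs"},
}
"""

_FRANK_REV_P_AB_CSTR = """\
modelname = 'Frank-Rev-P-AB-CSTR'
species = ['L', 'D', 'A', 'B', 'P']
reactions = [
    "      ->   A",    # 0   inflow
    "      ->   B",    # 1   inflow
    "A + B <->  L",    # 2, 3
    "A + B <->  D",    # 4, 5
    "A + L <-> 2 L",   # 6, 7
    "A + D <-> 2 D",   # 8, 9
    "L + D <->  P",    # 10, 11
    "A     ->    ",    # 12  CSTR outflow
    "B     ->    ",    # 13
    "L     ->    ",    # 14
    "D     ->    ",    # 15
    "P     ->    ",    # 16
]
# all CSTR outflows share the common flow rate
dual_pairs = [(12, 13), (12, 14), (12, 15), (12, 16)]
"""

_FRANK_REV_P = """\
modelname = 'Frank-Rev-P'
species = ['L', 'D', 'A', 'B', 'P']
reactions = [
    "A + B <->  L",    # 0, 1
    "A + B <->  D",    # 2, 3
    "A + L <-> 2 L",   # 4, 5
    "A + D <-> 2 D",   # 6, 7
    "L + D <->  P",    # 8, 9
]
"""

_REPLICATOR = """\
modelname = 'Replicator-Hochberg-Ribo'
species = ['1RD', '1RL', '2RD', '2RL', 'A']
reactions = [
    "A + 1RD + 2RD <-> 2 1RD + 2RD",   # 0, 1
    "A + 1RL + 2RL <-> 2 1RL + 2RL",   # 2, 3
    "A + 2RD + 1RD <-> 2 2RD + 1RD",   # 4, 5
    "A + 2RL + 1RL <-> 2 2RL + 1RL",   # 6, 7
    "1RD ->   ",                        # 8
    "1RL ->   ",                        # 9
    "2RD ->   ",                        # 10
    "2RL ->   ",                        # 11
    "    ->  A",                        # 12
    "A   ->   ",                        # 13
]
enantiomeric_pairs = [(0, 1), (2, 3)]
# Mirror pairs across the second enantiomeric pair, the shared replication
# rate of the two cross-catalytic channels, and the common CSTR flow.
dual_pairs = [
    (0, 2), (0, 4), (0, 6),
    (1, 3), (1, 5), (1, 7),
    (8, 10), (8, 11), (8, 13),
]
"""

_BLANCO_LES = """\
modelname = 'Blanco-et-al-LES-2013'
species = ['L', 'D', 'A']
reactions = [
    "A     <->     L",   # 0, 1   direct synthesis / decomposition
    "A     <->     D",   # 2, 3
    "A + L <->   2 L",   # 4, 5   autocatalysis
    "A + D <->   2 D",   # 6, 7
    "A + L <-> L + D",   # 8, 9   limited enantioselectivity
    "A + D <-> D + L",   # 10, 11
]
"""

_CALVIN_LES = """\
modelname = 'Calvin-2-CSTR-LES'
species = ['LA', 'DA', 'LB', 'DB', 'NR3', 'AllylX']
reactions = [
    "            ->       NR3",   # 0   inflow
    "            ->    AllylX",   # 1   inflow
    "NR3 + AllylX <->      LA",   # 2, 3
    "NR3 + AllylX <->      DA",   # 4, 5
    "LA          <->       LB",   # 6, 7
    "DA          <->       DB",   # 8, 9
    "LA + LB     <->    2 LB",    # 10, 11  autocatalysis
    "DA + DB     <->    2 DB",    # 12, 13
    "LA + LB     <-> LB + DB",    # 14, 15  limited enantioselectivity
    "DA + DB     <-> DB + LB",    # 16, 17
    "LA  -> ",                    # 18  outflows
    "DA  -> ",                    # 19
    "LB  -> ",                    # 20
    "DB  -> ",                    # 21
    "NR3 -> ",                    # 22
    "AllylX -> ",                 # 23
]
enantiomeric_pairs = [(0, 1), (2, 3)]
dual_pairs = [
    (2, 4), (3, 5), (6, 8), (7, 9), (10, 12), (11, 13), (14, 16), (15, 17),
    (18, 19), (20, 21), (22, 23),
]
"""

_APED_DIMERIZATION = """\
modelname = 'APED-dimerization'
species = ['L', 'D', 'Lact', 'Dact', 'LL', 'DD', 'LD', 'DL']
reactions = [
    "Lact + L -> LL",   # 0  rate p
    "Dact + L -> DL",   # 1  rate alpha*p
    "Lact + D -> LD",   # 2  rate alpha*p
    "Dact + D -> DD",   # 3  rate p
]
enantiomeric_pairs = [(0, 1), (2, 3), (4, 5), (6, 7)]
dual_pairs = [(0, 3), (1, 2)]
"""

_APED_DIMERIZATION_ALPHA1 = _APED_DIMERIZATION.replace(
    "modelname = 'APED-dimerization'",
    "modelname = 'APED-dimerization-alpha1'",
).replace(
    "dual_pairs = [(0, 3), (1, 2)]",
    "dual_pairs = [(0, 1), (0, 2), (0, 3)]  # alpha = 1",
)

_BLACKMOND_SCHEME8 = """\
modelname = 'Blackmond-Scheme8'
species = ['R', 'S', 'A', 'Z', 'RR', 'SS', 'SR']
reactions = [
    "A + Z      ->      R",   # 0
    "A + Z      ->      S",   # 1
    "A + Z + R  ->    2 R",   # 2
    "A + Z + S  ->    2 S",   # 3
    "A + Z + RR -> R + RR",   # 4
    "A + Z + SS -> S + SS",   # 5
    "A + Z + SR -> R + SR",   # 6
    "A + Z + SR -> S + SR",   # 7
]
enantiomeric_pairs = [(0, 1), (4, 5)]
dual_pairs = [(0, 1), (2, 3), (4, 5), (6, 7)]
"""

_BLACKMOND_REV_2020 = """\
modelname = 'Blackmond-Rev-2020'
species = ['R', 'S', 'A', 'Z', 'RR', 'SS', 'SR']
reactions = [
    "A + Z      <->      R",   # 0, 1
    "A + Z      <->      S",   # 2, 3
    "A + Z + R  <->    2 R",   # 4, 5
    "A + Z + S  <->    2 S",   # 6, 7
    "R + R      <->     RR",   # 8, 9
    "S + S      <->     SS",   # 10, 11
    "R + S      <->     SR",   # 12, 13
    "A + Z + RR <-> R + RR",   # 14, 15
    "A + Z + SS <-> S + SS",   # 16, 17
    "A + Z + SR <-> R + SR",   # 18, 19
    "A + Z + SR <-> S + SR",   # 20, 21
]
enantiomeric_pairs = [(0, 1), (4, 5)]
dual_pairs = [(8, 10), (9, 11), (14, 16), (15, 17), (18, 20), (19, 21)]
"""

_FIXTURES: dict[str, str] = {
    "Kondepudi-Nelson": _KONDEPUDI_NELSON,
    "Frank-Rev-P-AB-CSTR": _FRANK_REV_P_AB_CSTR,
    "Frank-Rev-P": _FRANK_REV_P,
    "Replicator-Hochberg-Ribo": _REPLICATOR,
    "Blanco-et-al-LES-2013": _BLANCO_LES,
    "Calvin-2-CSTR-LES": _CALVIN_LES,
    "APED-dimerization": _APED_DIMERIZATION,
    "APED-dimerization-alpha1": _APED_DIMERIZATION_ALPHA1,
    "Blackmond-Scheme8": _BLACKMOND_SCHEME8,
    "Blackmond-Rev-2020": _BLACKMOND_REV_2020,
}


def list_fixtures() -> list[str]:
    return sorted(_FIXTURES)


def fixture_text(name: str) -> str:
    """The raw model-file text of a bundled fixture."""
    try:
        return _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(list_fixtures())}"
        ) from None


def load_fixture(name: str, dual_pairs=None, with_options: bool = False):
    """Load a bundled mechanism by name.

    ``dual_pairs`` overrides the fixture's declared dual pairs (used e.g. to
    force autocatalytic and limited-enantioselectivity rates equal).  With
    ``with_options`` the per-algorithm option map is returned as well.
    """
    text = fixture_text(name)
    network, options = parse_model(text)
    if dual_pairs is not None:
        from .network_model import build_network

        network = build_network(
            name=network.name,
            species_names=network.species_names,
            reaction_lines=_reaction_lines(text),
            enantiomeric_pairs=network.enantiomeric_pairs,
            dual_pairs=dual_pairs,
        )
    return (network, options) if with_options else network


def _reaction_lines(text: str) -> list[str]:
    import ast

    from .network_model import _split_assignments, _strip_comments

    for key, raw in _split_assignments(_strip_comments(text)):
        if key == "reactions":
            return list(ast.literal_eval(raw.strip()))
    raise KeyError("no reactions block")


def load_model_file(path: str, strict: bool = False) -> ReactionNetwork:
    """Load a user-provided model file in the bundled fixtures' format."""
    network, _ = parse_model(path, strict=strict)
    return network
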