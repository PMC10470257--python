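"""Parsing and representation of mass-action reaction mechanisms.

A mechanism is an ordered species list (the first two species must be an
enantiomeric pair), an ordered reaction list, and a set of *dual pairs*:
reactions that map onto each other under the enantiomer swap and therefore
must share the same rate constant.  Multi-way rate equalities (e.g. the
common flow rate of CSTR pseudo-reactions) are normalised to pairs sharing
the same first element: ``(1, 2), (1, 3), (1, 4), ...``.
"""

from __future__ import annotations

import ast
import warnings
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence


class ModelParseError(ValueError):
    """Raised when a model file or reaction line cannot be parsed."""


class ValidationError(ValueError):
    """Raised when a parsed mechanism violates a structural invariant."""


#: partner_index value for species without an enantiomer
ACHIRAL = "achiral"


@dataclass(frozen=True)
class Species:
    name: str
    index: int
    partner_index: int | str = ACHIRAL

    @property
    def is_chiral(self) -> bool:
        return self.partner_index != ACHIRAL


@dataclass(frozen=True)
class Reaction:
    """A single irreversible reaction.

    ``reactants`` and ``products`` are sorted tuples of
    ``(species_index, coefficient)`` with positive integer coefficients.
    Either side may be empty (inflow/outflow pseudo-reactions).
    """

    index: int
    reactants: tuple[tuple[int, int], ...]
    products: tuple[tuple[int, int], ...]

    @property
    def rate_symbol(self) -> str:
        return f"k{self.index}"

    def reactant_count(self, species_index: int) -> int:
        return dict(self.reactants).get(species_index, 0)

    def product_count(self, species_index: int) -> int:
        return dict(self.products).get(species_index, 0)

    def net(self, species_index: int) -> int:
        return self.product_count(species_index) - self.reactant_count(species_index)


def parse_reaction(line: str) -> tuple[Counter, Counter, bool]:
    """Parse one reaction line into reactant/product multisets.

    Grammar: ``side := '' | term ('+' term)*``; ``term := [int] name``;
    the arrow is ``->`` (irreversible) or ``<->`` (reversible).
    Coefficients are space-separated integers (``2 L``), defaulting to 1.
    """
    if "<->" in line:
        parts = line.split("<->")
        reversible = True
    elif "->" in line:
        parts = line.split("->")
        reversible = False
    else:
        raise ModelParseError(f"missing or malformed arrow in reaction {line!r}")
    if len(parts) != 2:
        raise ModelParseError(f"more than one arrow in reaction {line!r}")
    reactants = _parse_side(parts[0], line)
    products = _parse_side(parts[1], line)
    return reactants, products, reversible


def _parse_side(text: str, line: str) -> Counter:
    side: Counter = Counter()
    text = text.strip()
    if not text:
        return side
    for term in text.split("+"):
        tokens = term.split()
        if len(tokens) == 1:
            coeff, name = 1, tokens[0]
        elif len(tokens) == 2:
            if not tokens[0].isdigit():
                raise ModelParseError(
                    f"bad coefficient {tokens[0]!r} in reaction {line!r}"
                )
            coeff, name = int(tokens[0]), tokens[1]
        else:
            raise ModelParseError(f"malformed term {term!r} in reaction {line!r}")
        if name.isdigit():
            raise ModelParseError(
                f"coefficient {name!r} without species name in reaction {line!r}"
            )
        if coeff < 1:
            raise ModelParseError(
                f"non-positive coefficient in term {term!r} of reaction {line!r}"
            )
        side[name] += coeff
    return side


def expand_reversibles(
    parsed_lines: Sequence[tuple[Counter, Counter, bool]],
) -> list[tuple[Counter, Counter]]:
    """Expand reversible lines per-line: forward then backward, in file order."""
    out: list[tuple[Counter, Counter]] = []
    for reactants, products, reversible in parsed_lines:
        out.append((reactants, products))
        if reversible:
            out.append((products, reactants))
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)

    def classes(self) -> list[tuple[int, ...]]:
        groups: dict[int, list[int]] = {}
        for i in range(len(self.parent)):
            groups.setdefault(self.find(i), []).append(i)
        return [tuple(sorted(g)) for g in sorted(groups.values()) if len(g) > 1]


def _normalize_classes(classes: Iterable[tuple[int, ...]]) -> list[tuple[int, int]]:
    """Encode equality classes as pairs sharing the same first element."""
    pairs: list[tuple[int, int]] = []
    for cls in sorted(classes):
        first = cls[0]
        pairs.extend((first, other) for other in cls[1:])
    return sorted(pairs)


@dataclass
class ReactionNetwork:
    name: str
    species: list[Species]
    reactions: list[Reaction]
    enantiomeric_pairs: list[tuple[int, int]]
    dual_pairs: list[tuple[int, int]] = field(default_factory=list)

    # ------------------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def regular_reactions(self) -> list[int]:
        in_pair = {i for pair in self.dual_pairs for i in pair}
        return [r.index for r in self.reactions if r.index not in in_pair]

    @property
    def dual_classes(self) -> list[tuple[int, ...]]:
        uf = _UnionFind(self.n_reactions)
        for a, b in self.dual_pairs:
            uf.union(a, b)
        return uf.classes()

    def rate_representative(self) -> dict[int, int]:
        """Map each reaction index to the smallest index of its rate class."""
        rep = {i: i for i in range(self.n_reactions)}
        for cls in self.dual_classes:
            for i in cls:
                rep[i] = cls[0]
        return rep

    # ------------------------------------------------------------------
    def species_swap_permutation(self, pairs: Sequence[tuple[int, int]] | None = None
                                 ) -> list[int]:
        """Permutation of species indices swapping each enantiomeric pair."""
        pairs = self.enantiomeric_pairs if pairs is None else pairs
        perm = list(range(self.n_species))
        for a, b in pairs:
            perm[a], perm[b] = b, a
        return perm

    def mirror_reaction_index(self, reaction_index: int,
                              pairs: Sequence[tuple[int, int]] | None = None
                              ) -> int | None:
        """Index of the mirror image of a reaction under the species swap."""
        perm = self.species_swap_permutation(pairs)
        rxn = self.reactions[reaction_index]
        mirrored = (_apply_perm(rxn.reactants, perm), _apply_perm(rxn.products, perm))
        for other in self.reactions:
            if (other.reactants, other.products) == mirrored:
                return other.index
        return None

    # ------------------------------------------------------------------
    def validate(self) -> None:
        names = self.species_names
        if len(names) != len(set(names)):
            raise ValidationError("species names are not unique")
        if self.n_species < 2:
            raise ValidationError("a mechanism needs at least 2 species")
        if not self.reactions:
            raise ValidationError("empty reaction list")
        if not self.enantiomeric_pairs or set(self.enantiomeric_pairs[0]) != {0, 1}:
            raise ValidationError("the first two species must be an enantiomeric pair")
        seen: set[int] = set()
        for a, b in self.enantiomeric_pairs:
            if a == b or not (0 <= a < self.n_species and 0 <= b < self.n_species):
                raise ValidationError(f"invalid enantiomeric pair ({a}, {b})")
            if a in seen or b in seen:
                raise ValidationError("species assigned to more than one pair")
            seen |= {a, b}
        for a, b in self.dual_pairs:
            if a == b or not (0 <= a < self.n_reactions and 0 <= b < self.n_reactions):
                raise ValidationError(f"invalid dual pair ({a}, {b})")
        # Rate classes must be closed under the full enantiomer swap, else
        # the mirror symmetry of the kinetics is broken by construction.
        for cls in self.dual_classes:
            image = set()
            for i in cls:
                j = self.mirror_reaction_index(i)
                if j is None:
                    raise ValidationError(
                        f"reaction {i} is in a dual class but has no mirror image "
                        "under the declared enantiomeric pairs"
                    )
                image.add(j)
            if image != set(cls):
                raise ValidationError(
                    f"dual class {cls} is not closed under the enantiomer swap "
                    f"(image {tuple(sorted(image))}); check the declared dual pairs"
                )

    # ------------------------------------------------------------------
    def to_text(self) -> str:
        lines = [f"modelname = {self.name!r}", f"species = {self.species_names!r}"]
        rxn_lines = []
        for r in self.reactions:
            rxn_lines.append(f"    {format_reaction(self, r.index)!r},")
        lines.append("reactions = [\n" + "\n".join(rxn_lines) + "\n]")
        lines.append(f"enantiomeric_pairs = {self.enantiomeric_pairs!r}")
        lines.append(f"dual_pairs = {self.dual_pairs!r}")
        return "\n".join(lines) + "\n"


def _apply_perm(side: tuple[tuple[int, int], ...], perm: Sequence[int]
                ) -> tuple[tuple[int, int], ...]:
    return tuple(sorted((perm[s], c) for s, c in side))


def format_reaction(network: ReactionNetwork, index: int) -> str:
    rxn = network.reactions[index]

    def fmt(side: tuple[tuple[int, int], ...]) -> str:
        terms = []
        for s, c in side:
            name = network.species[s].name
            terms.append(name if c == 1 else f"{c} {name}")
        return " + ".join(terms)

    return f"{fmt(rxn.reactants)} -> {fmt(rxn.products)}"


def detect_dual_pairs(
    network: ReactionNetwork,
    declared: Sequence[tuple[int, int]] = (),
) -> list[tuple[int, int]]:
    """Detect dual reaction pairs from the first enantiomeric pair.

    A pair ``(i, j)`` with ``i < j`` is dual when swapping the two species of
    the first enantiomeric pair in reaction ``i`` yields exactly reaction
    ``j``.  Reactions invariant under the swap are regular.  User-declared
    pairs (needed for extra enantiomeric pairs and for multi-way rate
    equalities such as a common CSTR flow) are merged in, and the result is
    normalised to shared-first-element pairs.
    """
    first = network.enantiomeric_pairs[0]
    uf = _UnionFind(network.n_reactions)
    for rxn in network.reactions:
        j = network.mirror_reaction_index(rxn.index, pairs=[first])
        if j is not None and j != rxn.index:
            uf.union(rxn.index, j)
    for a, b in declared:
        if not (0 <= a < network.n_reactions and 0 <= b < network.n_reactions):
            raise ValidationError(f"declared dual pair ({a}, {b}) out of range")
        uf.union(a, b)
    return _normalize_classes(uf.classes())


def build_network(
    name: str,
    species_names: Sequence[str],
    reaction_lines: Sequence[str],
    enantiomeric_pairs: Sequence[tuple[int, int]] | None = None,
    dual_pairs: Sequence[tuple[int, int]] | None = None,
) -> ReactionNetwork:
    """Assemble and validate a :class:`ReactionNetwork` from text parts."""
    if len(species_names) < 2:
        raise ValidationError("a mechanism needs at least 2 species")
    index = {n: i for i, n in enumerate(species_names)}
    if len(index) != len(species_names):
        raise ValidationError("species names are not unique")

    parsed = [parse_reaction(line) for line in reaction_lines]
    expanded = expand_reversibles(parsed)
    if not expanded:
        raise ValidationError("empty reaction list")

    reactions = []
    for i, (reactants, products) in enumerate(expanded):
        for nm in list(reactants) + list(products):
            if nm not in index:
                raise ModelParseError(f"unknown species {nm!r} in reaction {i}")
        reactions.append(
            Reaction(
                index=i,
                reactants=tuple(sorted((index[n], c) for n, c in reactants.items())),
                products=tuple(sorted((index[n], c) for n, c in products.items())),
            )
        )

    pairs = [tuple(p) for p in (enantiomeric_pairs or [(0, 1)])]
    partner: dict[int, int | str] = {}
    for a, b in pairs:
        partner[a], partner[b] = b, a
    species = [
        Species(name=n, index=i, partner_index=partner.get(i, ACHIRAL))
        for i, n in enumerate(species_names)
    ]

    network = ReactionNetwork(
        name=name,
        species=species,
        reactions=reactions,
        enantiomeric_pairs=pairs,
    )
    network.dual_pairs = detect_dual_pairs(network, declared=dual_pairs or ())
    network.validate()
    return network


# ----------------------------------------------------------------------
# model files
# ----------------------------------------------------------------------

_KNOWN_KEYS = {"modelname", "species", "reactions", "dual_pairs",
               "enantiomeric_pairs", "analyses"}

_KNOWN_OPTION_KEYS = {
    "enabled", "num-samples", "dual-pairs-in-ec", "instability-heuristic",
    "sum-mineurs", "max-mineur-search-stop", "simplification-tries",
    "samples-folder", "samples-for-proportion", "enantiomeric-pairs",
    "2by2-jacobian", "plot", "time-to-show-plot",
}

DEFAULT_OPTIONS: Mapping[str, object] = {
    "enabled": True,
    "num-samples": 10,
    "dual-pairs-in-ec": True,
    "instability-heuristic": "mineurs",
    "sum-mineurs": True,
    "max-mineur-search-stop": 5,
    "simplification-tries": 10000,
    "samples-folder": None,
    "samples-for-proportion": None,
    "2by2-jacobian": True,
    "plot": False,
    "time-to-show-plot": 0.3,
}


def _strip_comments(text: str) -> str:
    out = []
    for line in text.splitlines():
        buf = []
        quote = None
        for ch in line:
            if quote is None and ch == "#":
                break
            if ch in "'\"" and quote is None:
                quote = ch
            elif ch == quote:
                quote = None
            buf.append(ch)
        out.append("".join(buf))
    return "\n".join(out)


def _split_assignments(text: str) -> list[tuple[str, str]]:
    """Split ``key = value`` assignments where values may span lines."""
    assignments: list[tuple[str, str]] = []
    key = None
    value_lines: list[str] = []
    depth = 0
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if depth == 0 and "=" in line and not stripped.startswith(("[", "{", "(")):
            if key is not None:
                assignments.append((key, "\n".join(value_lines)))
            key, _, rhs = line.partition("=")
            key = key.strip()
            value_lines = [rhs]
            depth = _net_depth(rhs)
        else:
            if key is None:
                raise ModelParseError(f"unexpected line outside assignment: {line!r}")
            value_lines.append(line)
            depth += _net_depth(line)
    if key is not None:
        assignments.append((key, "\n".join(value_lines)))
    return assignments


def _net_depth(fragment: str) -> int:
    depth = 0
    quote = None
    for ch in fragment:
        if quote:
            if ch == quote:
                quote = None
        elif ch in "'\"":
            quote = ch
        elif ch in "([{":
            depth += 1
        elif ch in ")]}":
            depth -= 1
    return depth


def parse_model(
    source: str, *, strict: bool = False
) -> tuple[ReactionNetwork, dict[str, dict[str, object]]]:
    """Parse a model file (text or path) into a network and an option map.

    The file dialect is a restricted key/value format: ``modelname``,
    ``species`` and ``reactions`` are mandatory; ``dual_pairs``,
    ``enantiomeric_pairs`` and per-algorithm ``analyses`` blocks are
    optional.  Values are Python literals, evaluated with
    :func:`ast.literal_eval` (never executed).  Unknown keys warn, or fail
    when ``strict`` is set.
    """
    import os

    if "\n" not in source and os.path.exists(source):
        with open(source) as fh:
            source = fh.read()

    values: dict[str, object] = {}
    for key, raw in _split_assignments(_strip_comments(source)):
        try:
            values[key] = ast.literal_eval(raw.strip())
        except (ValueError, SyntaxError) as exc:
            raise ModelParseError(f"cannot parse value for {key!r}: {exc}") from exc
        if key not in _KNOWN_KEYS:
            msg = f"unknown model file key {key!r}"
            if strict:
                raise ModelParseError(msg)
            warnings.warn(msg, stacklevel=2)

    for mandatory in ("modelname", "species", "reactions"):
        if mandatory not in values:
            raise ModelParseError(f"model file is missing {mandatory!r}")

    network = build_network(
        name=values["modelname"],
        species_names=list(values["species"]),
        reaction_lines=list(values["reactions"]),
        enantiomeric_pairs=values.get("enantiomeric_pairs"),
        dual_pairs=values.get("dual_pairs"),
    )

    options: dict[str, dict[str, object]] = {}
    for algo, block in (values.get("analyses") or {}).items():
        options[algo] = dict(block)
        for opt in block:
            if opt not in _KNOWN_OPTION_KEYS:
                msg = f"unknown option {opt!r} in analysis block {algo!r}"
                if strict:
                    raise ModelParseError(msg)
                warnings.warn(msg, stacklevel=2)
    return network, options
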