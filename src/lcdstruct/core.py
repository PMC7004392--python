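"""Core domain objects shared by every analysis stage.

The unit of analysis throughout the package is a single protein chain carrying
three aligned per-residue annotations: the amino-acid sequence, a raw
secondary-structure state string (DSSP-style one-letter codes), and a boolean
disorder mask marking residues that are present in the sequence but unresolved
in the deposited structure.  Raw structure codes are grouped into analysis
categories through a :class:`CategoryMap`; a disorder flag always overrides the
structure code, because an unresolved residue has no observed conformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: The 20 canonical amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
N_AA = 20

#: Placeholder for any non-canonical residue; windows containing it are
#: excluded from all composition statistics.
UNKNOWN_AA = "X"

#: Internal coil symbol.  Input dialects vary (space, '-', 'C', '~'); all are
#: normalised to this character on read.
COIL = "-"
COIL_ALIASES = frozenset({" ", "-", "C", "~"})

#: Raw structure-state alphabet after normalisation.
SS_ALPHABET = frozenset("HGIEBTS") | {COIL}

# Physicochemical groupings used for grouped LCD abundance summaries.
HYDROPHOBIC = frozenset("AILMV")
CHARGED = frozenset("DEHKR")
POLAR = frozenset("CNQST")
AROMATIC = frozenset("FWY")
PHYSICOCHEMICAL_GROUPS: dict[str, frozenset[str]] = {
    "hydrophobic": HYDROPHOBIC,
    "charged": CHARGED,
    "polar": POLAR,
    "aromatic": AROMATIC,
    "hydrophilic": CHARGED | POLAR,
}

# Charge sets for the opposite-charge co-occurrence filter.  Histidine is only
# partially protonated at physiological pH and is excluded by default.
POSITIVE_RESIDUES = frozenset("KR")
NEGATIVE_RESIDUES = frozenset("DE")


def normalize_ss(ss: str) -> str:
    """Normalise a raw structure string: coil aliases become :data:`COIL`."""
    out = []
    for ch in ss:
        if ch in COIL_ALIASES:
            out.append(COIL)
        elif ch in SS_ALPHABET:
            out.append(ch)
        else:
            raise ValueError(f"unknown secondary-structure code {ch!r}")
    return "".join(out)


def normalize_sequence(seq: str) -> str:
    """Uppercase a sequence and map every non-canonical letter to 'X'."""
    seq = seq.upper()
    return "".join(ch if ch in AA_INDEX else UNKNOWN_AA for ch in seq)


def sequence_indices(sequence: str) -> np.ndarray:
    """Encode a sequence as int8 indices into :data:`AMINO_ACIDS`; 'X' -> 20."""
    return np.frombuffer(
        sequence.translate(_SEQ_TRANSLATION).encode("latin-1"), dtype=np.uint8
    ).astype(np.int8)


_SEQ_TRANSLATION = str.maketrans(
    AMINO_ACIDS + UNKNOWN_AA,
    "".join(chr(i) for i in range(N_AA)) + chr(N_AA),
)


@dataclass(frozen=True, eq=False)
class AnnotatedChain:
    """One protein chain with aligned per-residue annotations.

    Parameters
    ----------
    chain_id :
        Identifier such as ``"1ABC_A"``.
    sequence :
        Residues over the canonical alphabet plus ``'X'`` for non-canonical.
    ss_states :
        Per-residue structure codes over ``{H,G,I,E,B,T,S,-}`` (normalised).
    disorder_mask :
        Boolean per-residue array; ``True`` marks unresolved/disordered
        residues.
    """

    chain_id: str
    sequence: str
    ss_states: str
    disorder_mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        object.__setattr__(self, "ss_states", normalize_ss(self.ss_states))
        object.__setattr__(
            self, "disorder_mask", np.asarray(self.disorder_mask, dtype=bool)
        )
        n = len(self.sequence)
        if n == 0:
            raise ValueError(f"{self.chain_id}: empty sequence")
        if len(self.ss_states) != n or len(self.disorder_mask) != n:
            raise ValueError(
                f"{self.chain_id}: annotation lengths differ "
                f"(seq {n}, secstr {len(self.ss_states)}, "
                f"disorder {len(self.disorder_mask)})"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotatedChain):
            return NotImplemented
        return (
            self.chain_id == other.chain_id
            and self.sequence == other.sequence
            and self.ss_states == other.ss_states
            and bool(np.array_equal(self.disorder_mask, other.disorder_mask))
        )

    def __hash__(self) -> int:  # identity-free hash over immutable fields
        return hash((self.chain_id, self.sequence, self.ss_states))

    def subchain(self, start: int, end: int) -> "AnnotatedChain":
        """Return the chain restricted to ``[start, end)`` (same id)."""
        return AnnotatedChain(
            chain_id=self.chain_id,
            sequence=self.sequence[start:end],
            ss_states=self.ss_states[start:end],
            disorder_mask=self.disorder_mask[start:end],
        )

    @property
    def seq_indices(self) -> np.ndarray:
        return sequence_indices(self.sequence)


#: Default grouping of raw structure codes into analysis categories.  The
#: 3-10/pi helices, isolated bridges and turn/bend states are kept distinct
#: from the main helix/sheet categories; callers may merge them via
#: :meth:`CategoryMap.merged`.
DEFAULT_CATEGORY_CODES: tuple[tuple[str, frozenset[str]], ...] = (
    ("alpha_helix", frozenset("H")),
    ("beta_sheet", frozenset("E")),
    ("helix_310_pi", frozenset("GI")),
    ("bridge", frozenset("B")),
    ("turn_bend", frozenset("TS")),
    ("loop_irregular", frozenset({COIL})),
)

DISORDER_CATEGORY = "disorder"


@dataclass(frozen=True)
class CategoryMap:
    """Named mapping from raw structure codes to analysis categories.

    Every raw code maps to exactly one category; the disorder flag overrides
    any code and is always the final category.
    """

    categories: tuple[tuple[str, frozenset[str]], ...] = DEFAULT_CATEGORY_CODES

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, codes in self.categories:
            if name == DISORDER_CATEGORY:
                raise ValueError("'disorder' is reserved for the mask override")
            if seen & codes:
                raise ValueError(f"category {name!r} re-maps codes {seen & codes}")
            seen |= codes
        if seen != SS_ALPHABET:
            raise ValueError(f"categories must partition {sorted(SS_ALPHABET)}")

    @classmethod
    def default(cls) -> "CategoryMap":
        return cls()

    @property
    def names(self) -> tuple[str, ...]:
        """Category names in canonical order; disorder is last."""
        return tuple(n for n, _ in self.categories) + (DISORDER_CATEGORY,)

    @property
    def n_categories(self) -> int:
        return len(self.categories) + 1

    @property
    def disorder_index(self) -> int:
        return len(self.categories)

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def merged(self, merges: dict[str, tuple[str, ...]]) -> "CategoryMap":
        """Return a map in which the named categories are fused.

        ``merges`` maps each new category name to the existing names it
        absorbs; unmentioned categories are preserved in order.
        """
        absorbed = {old for olds in merges.values() for old in olds}
        current = dict(self.categories)
        out: list[tuple[str, frozenset[str]]] = []
        for name, codes in self.categories:
            if name in absorbed:
                continue
            out.append((name, codes))
        for new, olds in merges.items():
            fused: frozenset[str] = frozenset()
            for old in olds:
                fused |= current[old]
            out.append((new, fused))
        return CategoryMap(tuple(out))

    def residue_categories(self, chain: AnnotatedChain) -> np.ndarray:
        """Per-residue category indices; disorder overrides the raw code."""
        code_to_idx = {
            code: i for i, (_, codes) in enumerate(self.categories) for code in codes
        }
        idx = np.fromiter(
            (code_to_idx[ch] for ch in chain.ss_states),
            dtype=np.int8,
            count=len(chain),
        )
        idx[chain.disorder_mask] = self.disorder_index
        return idx
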