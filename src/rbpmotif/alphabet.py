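"""Structural-context annotation alphabets.

Each base of an RNA is annotated with a single-character label describing the
secondary-structure context it sits in.  The default alphabet is PLUM:
paired (P), hairpin loop (L), unstructured/external (U) and miscellaneous (M,
collapsing bulges, internal loops and multiloops).  A single-letter alphabet
(every context mapped to one label) gives a structure-naive model and is used
for ablation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The six structural categories a base can be assigned to.
CATEGORIES = (
    "paired",
    "hairpin_loop",
    "external",
    "bulge",
    "internal_loop",
    "multiloop",
)


@dataclass(frozen=True)
class AnnotationAlphabet:
    """Ordered set of context letters plus the category -> letter mapping."""

    letters: tuple[str, ...]
    category_map: dict[str, str] = field(compare=False)

    def __post_init__(self) -> None:
        if len(set(self.letters)) != len(self.letters):
            raise ValueError("alphabet letters must be unique")
        missing = [c for c in CATEGORIES if c not in self.category_map]
        if missing:
            raise ValueError(f"category_map missing categories: {missing}")
        mapped = set(self.category_map.values())
        if mapped != set(self.letters):
            raise ValueError(
                "letters must contain exactly the mapped letters: "
                f"{sorted(mapped)} vs {list(self.letters)}"
            )

    def __len__(self) -> int:
        return len(self.letters)

    def index(self, letter: str) -> int:
        return self.letters.index(letter)

    def letter_of(self, category: str) -> str:
        return self.category_map[category]

    def row_of(self, category: str) -> int:
        """Row index in an annotation profile for a structural category."""
        return self.index(self.category_map[category])

    @property
    def name(self) -> str:
        return "".join(self.letters)


def plum_alphabet() -> AnnotationAlphabet:
    """The default four-letter alphabet: P, L, U, M."""
    return AnnotationAlphabet(
        letters=("P", "L", "U", "M"),
        category_map={
            "paired": "P",
            "hairpin_loop": "L",
            "external": "U",
            "bulge": "M",
            "internal_loop": "M",
            "multiloop": "M",
        },
    )


def single_letter_alphabet(letter: str = "S") -> AnnotationAlphabet:
    """Alphabet collapsing every context to one letter (structure-naive)."""
    return AnnotationAlphabet(
        letters=(letter,),
        category_map={c: letter for c in CATEGORIES},
    )
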