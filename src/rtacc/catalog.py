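"""Catalogue of the 18 game-based training tasks and their cognitive domains.

The computerized training platform delivers 3-minute game tasks drawn from
five cognitive domains: attention, working memory, executive function,
visuospatial ability, and language/calculation.  The default catalogue below
is the fixed task inventory the synthetic generator cycles through and the
leave-one-game-out sensitivity analysis iterates over.
"""

from __future__ import annotations

from dataclasses import dataclass

DOMAINS = (
    "attention",
    "working_memory",
    "executive_function",
    "visuospatial_ability",
    "language_calculation",
)


@dataclass(frozen=True)
class GameCatalogEntry:
    """One training game: a stable id, its display name, and its domain."""

    game_id: str
    name: str
    domain: str

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")


_DEFAULT_GAMES: tuple[tuple[str, str, str], ...] = (
    ("circles_order", "Tap the Circles in Order", "attention"),
    ("numbers_order", "Tap the Numbers in Order", "attention"),
    ("numbers_reverse", "Press the Number in Reverse Order", "attention"),
    ("circles_reverse", "Tap the Circles in Reverse Order", "working_memory"),
    ("grow_tomatoes", "Grow the Tomatoes", "working_memory"),
    ("pair_matching", "Pair Matching", "working_memory"),
    ("collect_fruit", "Quickly Collect the Fruit", "executive_function"),
    ("previous_card", "Remember the Previous Card", "executive_function"),
    ("treasure_hunt", "Treasure Hunt", "visuospatial_ability"),
    ("spot_difference", "Spot the Difference", "visuospatial_ability"),
    ("fishing_challenge", "Fishing Challenge", "visuospatial_ability"),
    ("merge_shapes", "Merge the Shapes", "visuospatial_ability"),
    ("box_sorting", "Colorful Box Sorting", "visuospatial_ability"),
    ("touch_card", "Touch-Touch Card Game", "visuospatial_ability"),
    ("arrival_time", "When Will It Arrive?", "language_calculation"),
    ("how_much", "How Much Is It?", "language_calculation"),
    ("reverse_calc", "Reverse Calculation", "language_calculation"),
    ("honeycomb", "Crack the Honeycomb", "language_calculation"),
)


def default_catalog() -> list[GameCatalogEntry]:
    """Return the default 18-game catalogue (deterministic constant).

    Three attention games, three working-memory games, two executive-function
    games, six visuospatial games, and four language/calculation games.
    """
    return [GameCatalogEntry(*row) for row in _DEFAULT_GAMES]


def catalog_domains(catalog: list[GameCatalogEntry] | None = None) -> dict[str, str]:
    """Map game_id -> domain for a catalogue (default catalogue if omitted)."""
    entries = catalog if catalog is not None else default_catalog()
    return {e.game_id: e.domain for e in entries}
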