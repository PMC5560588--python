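"""Shared tokenization and matching primitives.

Gene names are split into candidate neighbor words at a fixed delimiter set
(whitespace plus ``,;:/()-``), and dictionary surface forms are matched
against sentences under whole-token semantics: a hit may not sit inside a
longer alphanumeric-or-hyphen run, so the term ``AGING`` does not fire inside
``anti-aging`` (hyphenated variants are separate dictionary entries and are
matched literally).
"""

from __future__ import annotations

import re
from functools import lru_cache
from typing import Iterator

# Delimiters at which multiword gene names are split into tokens.
NAME_DELIMITERS = re.compile(r"[\s,;:/()\-]+")

# A token boundary for surface-form matching: the character before/after a
# hit may not be alphanumeric, underscore, or hyphen.  Hyphen is included so
# hyphenated dictionary entries stay distinct from their components.
_BOUNDARY_BEFORE = r"(?<![0-9A-Za-z_\-])"
_BOUNDARY_AFTER = r"(?![0-9A-Za-z_\-])"


def tokenize(text: str) -> list[str]:
    """Split *text* at the delimiter set, lowercased, dropping empties."""
    return [t.lower() for t in NAME_DELIMITERS.split(text) if t]


@lru_cache(maxsize=65536)
def surface_pattern(surface: str, case_sensitive: bool = False) -> re.Pattern:
    """Compile a whole-token pattern for one dictionary surface form.

    Internal whitespace is generalized to any whitespace run, so multiword
    forms match as contiguous token sequences.
    """
    parts = [re.escape(p) for p in surface.split()]
    body = r"\s+".join(parts)
    flags = 0 if case_sensitive else re.IGNORECASE
    return re.compile(_BOUNDARY_BEFORE + body + _BOUNDARY_AFTER, flags)


def find_surface(sentence: str, surface: str, case_sensitive: bool = False) -> bool:
    """Whole-token containment test of *surface* in *sentence*."""
    # Cheap substring prefilter before the anchored regex.
    if surface.lower() not in sentence.lower():
        return False
    return surface_pattern(surface, case_sensitive).search(sentence) is not None


def iter_surfaces(
    sentence: str, surfaces: Iterator[str], case_sensitive: bool = False
) -> Iterator[str]:
    """Yield the surface forms present in *sentence* under token boundaries."""
    lowered = sentence.lower()
    for surface in surfaces:
        if surface.lower() in lowered and surface_pattern(
            surface, case_sensitive
        ).search(sentence):
            yield surface
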