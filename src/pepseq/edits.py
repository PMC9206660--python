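"""Reference amplicon and programmed-edit description.

The screen's self-targeting pegRNA writes a fixed 6-nt substitution
(CCTCTG → GAATTC) into the linker next to the peptide barcode; read 2 of
each pair covers this target site. :class:`EditSpec` pins the reference
amplicon, the edit coordinates and both alleles, and is shared by the
simulator and the outcome classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_REF_ALLELE = "CCTCTG"
DEFAULT_ALT_ALLELE = "GAATTC"


@dataclass(frozen=True)
class EditSpec:
    """A reference amplicon plus the programmed edit within it.

    ``edit_start`` is 0-based; the edited region is the half-open interval
    ``[edit_start, edit_start + len(ref_allele))``. The default alleles are
    the linker edit (CCTCTG → GAATTC); arbitrary same- or different-length
    allele pairs are accepted as long as the reference allele matches the
    amplicon.
    """

    ref_amplicon: str
    edit_start: int
    ref_allele: str = DEFAULT_REF_ALLELE
    alt_allele: str = DEFAULT_ALT_ALLELE

    def __post_init__(self) -> None:
        region = self.ref_amplicon[self.edit_start : self.edit_start + len(self.ref_allele)]
        if region != self.ref_allele:
            raise ValueError(
                f"amplicon[{self.edit_start}:{self.edit_start + len(self.ref_allele)}] "
                f"= {region!r}, expected ref allele {self.ref_allele!r}"
            )

    @property
    def edit_end(self) -> int:
        return self.edit_start + len(self.ref_allele)

    @property
    def edited_amplicon(self) -> str:
        """The amplicon with the programmed edit fully installed."""
        return (
            self.ref_amplicon[: self.edit_start]
            + self.alt_allele
            + self.ref_amplicon[self.edit_end :]
        )


def default_edit_spec(
    flank5: int = 40, flank3: int = 54, seed: int = 20240131
) -> EditSpec:
    """A reproducible synthetic linker amplicon carrying the CCTCTG site.

    Flank sequences are drawn deterministically from ``seed``; with the
    default flanks the amplicon is 100 nt with the edit at position 40,
    which comfortably exercises the indel-flank and quality-masking rules.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    left = "".join(rng.choice(bases, flank5))
    right = "".join(rng.choice(bases, flank3))
    amplicon = left + DEFAULT_REF_ALLELE + right
    return EditSpec(ref_amplicon=amplicon, edit_start=flank5)
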