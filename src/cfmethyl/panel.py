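"""Marker panel definition for the ddMSP assay.

The assay panel comprises 12 methylation markers (four common breast-cancer
markers, four luminal-dominant and four triple-negative-dominant) plus four
internal-control (IC) amplicons.  The IC amplicons target CpG-free regions in
genes with copy-number alteration rates below 5%, so they report total cfDNA
concentration regardless of methylation status or tumour copy-number state.
"""

from __future__ import annotations

from dataclasses import dataclass, field


COMMON_MARKERS = ("JAK3", "RASGRF1", "CPXM1", "SHF")
LUMINAL_MARKERS = ("DNM3", "CAV2", "HOXA10", "B3GNT5")
TN_MARKERS = ("ST3GAL6", "DACH1", "P2RX3", "chr8:23572595")

METHYLATION_MARKERS = COMMON_MARKERS + LUMINAL_MARKERS + TN_MARKERS
INTERNAL_CONTROLS = ("CREM", "GLYATL3", "ELMOD3", "KLF9")


def _default_channel_map() -> dict[str, str]:
    # Duplex wells pair one FAM-labelled and one Alexa532-labelled reaction;
    # the exact dye assignment only matters for parsing droplet exports.
    channels = {}
    for i, m in enumerate(METHYLATION_MARKERS + INTERNAL_CONTROLS):
        channels[m] = "FAM" if i % 2 == 0 else "Alexa532"
    return channels


@dataclass(frozen=True)
class MarkerPanel:
    """The 12 + 4 marker panel with per-marker channel assignments."""

    methylation_markers: tuple[str, ...] = METHYLATION_MARKERS
    internal_controls: tuple[str, ...] = INTERNAL_CONTROLS
    channel_map: dict[str, str] = field(default_factory=_default_channel_map)

    def __post_init__(self) -> None:
        all_markers = self.methylation_markers + self.internal_controls
        if len(set(all_markers)) != len(all_markers):
            raise ValueError("panel markers must be distinct")
        missing = [m for m in all_markers if m not in self.channel_map]
        if missing:
            raise ValueError(f"markers without channel assignment: {missing}")

    @property
    def all_markers(self) -> tuple[str, ...]:
        return self.methylation_markers + self.internal_controls

    def dominance_class(self, marker: str) -> str:
        """Return 'common', 'luminal', 'tn' or 'ic' for a panel marker."""
        if marker in COMMON_MARKERS:
            return "common"
        if marker in LUMINAL_MARKERS:
            return "luminal"
        if marker in TN_MARKERS:
            return "tn"
        if marker in self.internal_controls:
            return "ic"
        raise KeyError(marker)


DEFAULT_PANEL = MarkerPanel()
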