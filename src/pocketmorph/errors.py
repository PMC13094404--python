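"""Exception hierarchy for pocketmorph."""


class PocketMorphError(Exception):
    """Base class for all pocketmorph errors."""


class StructureParseError(PocketMorphError):
    """A structure file could not be read or contained no atoms."""


class LigandSelectionError(PocketMorphError):
    """A ligand selector matched zero or more than one ligand instance."""


class DegeneratePocketError(PocketMorphError):
    """A pocket has too few atoms (or zero spatial extent) for shape analysis."""


class UndefinedEffectError(PocketMorphError):
    """An effect size is undefined (zero pooled spread)."""
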