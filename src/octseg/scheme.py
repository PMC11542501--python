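"""The 14-class labelling scheme for retinal OCT B-scans.

Ten retinal layers (ILM through RPE, top to bottom) plus four additional
features: the pre-retinal space above the ILM, the background below the RPE,
collapsed outer layers, and cysts.  The networks learn the first thirteen
classes; cysts (id 13) are added to predictions by post-processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field


CLASS_NAMES: tuple[str, ...] = (
    "preretinal_space",      # 0
    "ILM",                   # 1
    "RNFL",                  # 2
    "GCL",                   # 3
    "IPL",                   # 4
    "INL",                   # 5
    "OPL",                   # 6
    "ELM",                   # 7
    "PR1",                   # 8
    "PR2",                   # 9
    "RPE",                   # 10
    "background_below_RPE",  # 11
    "collapsed_layers",      # 12
    "cyst",                  # 13
)

#: ids of the ten anatomical layers, in top-to-bottom order
LAYER_IDS: tuple[int, ...] = tuple(range(1, 11))

PRERETINAL = 0
BACKGROUND = 11
COLLAPSED = 12
CYST = 13

#: classes a segmentation network is trained on
LEARNED_CLASSES: tuple[int, ...] = tuple(range(13))
#: classes added by post-processing only
POSTPROCESSED_CLASSES: tuple[int, ...] = (CYST,)

N_CLASSES = len(CLASS_NAMES)
N_LEARNED = len(LEARNED_CLASSES)


@dataclass(frozen=True)
class ClassScheme:
    """Ordered class names with integer ids and the learned/post-processed split."""

    names: tuple[str, ...] = CLASS_NAMES
    learned: tuple[int, ...] = LEARNED_CLASSES
    postprocessed: tuple[int, ...] = POSTPROCESSED_CLASSES
    name_to_id: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.names) != 14:
            raise ValueError("scheme must have exactly 14 classes")
        if len(self.learned) != 13:
            raise ValueError("exactly 13 classes are learned")
        if set(self.learned) & set(self.postprocessed):
            raise ValueError("learned and post-processed classes overlap")
        object.__setattr__(
            self, "name_to_id", {n: i for i, n in enumerate(self.names)}
        )

    @property
    def n_classes(self) -> int:
        return len(self.names)

    @property
    def n_learned(self) -> int:
        return len(self.learned)

    def id_of(self, name: str) -> int:
        return self.name_to_id[name]


DEFAULT_SCHEME = ClassScheme()
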