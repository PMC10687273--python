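"""Name-keyed registry of the nine solubility models."""

from __future__ import annotations

from .base import SolubilityModel
from .data import DomainError, SolubilityDataset
from .density import Bartle, Chrastil, MendezSantiagoTeja, ReddyGarlapati, Sodeifian
from .elm import ExpandedLiquid
from .preos import PengRobinson

#: name -> (model class, fixed constructor kwargs)
MODEL_REGISTRY: dict[str, tuple[type, dict]] = {
    "chrastil": (Chrastil, {}),
    "mt": (MendezSantiagoTeja, {}),
    "bartle": (Bartle, {}),
    "sodeifian": (Sodeifian, {}),
    "reddy-garlapati": (ReddyGarlapati, {}),
    "pr-eos": (PengRobinson, {}),
    "elm1": (ExpandedLiquid, {"case": 1}),
    "elm2": (ExpandedLiquid, {"case": 2}),
    "elm3": (ExpandedLiquid, {"case": 3}),
}

MODEL_NAMES = tuple(MODEL_REGISTRY)


def make_model(name: str, dataset: SolubilityDataset, **kwargs) -> SolubilityModel:
    """Instantiate a registered model on a dataset."""
    try:
        cls, fixed = MODEL_REGISTRY[name]
    except KeyError:
        raise DomainError(
            f"unknown model {name!r}; available: {', '.join(MODEL_NAMES)}"
        ) from None
    return cls(dataset, **{**fixed, **kwargs})
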