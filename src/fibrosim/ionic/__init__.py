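from .base import CellState, IonicModel, reaction_step, integrate_reaction, DT_O_DEFAULT
from .bondarenko import BondarenkoModel
from .surrogate import SurrogateModel

__all__ = [
    "CellState",
    "IonicModel",
    "reaction_step",
    "integrate_reaction",
    "DT_O_DEFAULT",
    "BondarenkoModel",
    "SurrogateModel",
    "get_model",
]


def get_model(name: str) -> IonicModel:
    """Model registry used by the CLI and config layer."""
    if name == "bondarenko":
        return BondarenkoModel()
    if name == "surrogate":
        return SurrogateModel()
    raise ValueError(f"unknown ionic model {name!r}")
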