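"""Serialization and the shipped pre-searched valid populations.

The package ships a pre-searched population of valid GC and BC models
(`dgnet/data/*.json`) so network experiments do not need to re-run the
stochastic search.  Each file records the search metadata (sample count,
seed, yield) and, per model, the sampled parameter dictionary and the
nine measurements computed at retention time.  ``load_valid_population``
rebuilds full :class:`~dgnet.neuron.NeuronModel` objects from the
parameters; every shipped model re-passes validation when re-measured
from scratch (asserted in the test suite).

Regenerate with ``python scripts/make_populations.py``.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from .ephys import MeasurementVector
from .mpmoss import ValidPopulation, build_model

__all__ = ["save_population", "load_population", "load_valid_population"]

_DATA_FILES = {"GC": "gc_population.json", "BC": "bc_population.json"}


def save_population(pop: ValidPopulation, path: Union[str, Path],
                    max_models: Optional[int] = None) -> None:
    """Write a population (optionally truncated) as JSON."""
    models = list(zip(pop.parameters, pop.measurements))
    if max_models is not None:
        models = models[:max_models]
    payload = {
        "cell_class": pop.cell_class,
        "n_sampled": pop.n_sampled,
        "seed": pop.seed,
        "n_valid_total": len(pop.models),
        "yield_fraction": pop.yield_fraction,
        "models": [
            {"params": params, "measurements": mv.as_dict()}
            for params, mv in models
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_population(path: Union[str, Path]) -> ValidPopulation:
    """Rebuild a :class:`ValidPopulation` from a JSON file."""
    payload = json.loads(Path(path).read_text())
    cell_class = payload["cell_class"]
    models, vectors, params = [], [], []
    for entry in payload["models"]:
        models.append(build_model(cell_class, entry["params"]))
        vectors.append(MeasurementVector(**entry["measurements"]))
        params.append(entry["params"])
    return ValidPopulation(cell_class, models, vectors, params,
                           payload["n_sampled"], payload["seed"])


def load_valid_population(cell_class: str) -> ValidPopulation:
    """Load the shipped pre-searched population for ``cell_class``."""
    if cell_class not in _DATA_FILES:
        raise ValueError(f"unknown cell class: {cell_class}")
    ref = resources.files("dgnet").joinpath("data", _DATA_FILES[cell_class])
    with resources.as_file(ref) as path:
        return load_population(path)
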