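"""Declarative model and corpus files (JSON or YAML).

A model file names a registered parametric family (model zoo) or a user
plugin hook and supplies its parameters; optional blocks override species
metadata, compartments and the initial state.  Drift code itself is never
serialized -- reconstruction goes through the family registry, which keeps
files small, text-only and reproducible.

Schema (unknown keys are rejected)::

    name: my_model                  # optional
    family: benchmark               # registered builder name, or
    plugin: mypkg.mymod:factory     # import-path hook returning an OdeModel
    params: {k1: 5.0, ...}          # keyword arguments of the builder
    species:                        # optional overrides, by name
      - {name: M, compartment: cell, unit: count}
    compartments:
      - {id: cell, volume_litres: 1.0e-15}
    initial_state: [0, 0]           # optional override
"""

from __future__ import annotations

import importlib
import json
from pathlib import Path

import yaml

from .model import Compartment, ModelError, OdeModel, Species
from .zoo import Corpus, CorpusSpec, FAMILY_BUILDERS, generate_corpus

__all__ = ["load_model_file", "save_corpus", "load_corpus_manifest",
           "build_model_from_config"]

_ALLOWED_KEYS = {"name", "family", "plugin", "params", "species",
                 "compartments", "initial_state"}


def _read_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def build_model_from_config(cfg: dict) -> OdeModel:
    unknown = set(cfg) - _ALLOWED_KEYS
    if unknown:
        raise ModelError(f"unknown keys in model config: {sorted(unknown)}")
    params = cfg.get("params", {}) or {}
    if "family" in cfg and "plugin" in cfg:
        raise ModelError("model config must set either 'family' or 'plugin', not both")
    if "family" in cfg:
        family = cfg["family"]
        builder = FAMILY_BUILDERS.get(family)
        if builder is None:
            raise ModelError(f"unknown model family {family!r}; registered: "
                             f"{sorted(FAMILY_BUILDERS)}")
    elif "plugin" in cfg:
        mod_name, _, attr = str(cfg["plugin"]).partition(":")
        if not attr:
            raise ModelError("plugin must be 'module.path:callable'")
        builder = getattr(importlib.import_module(mod_name), attr)
    else:
        raise ModelError("model config needs a 'family' or 'plugin' entry")
    model = builder(**params)
    if not isinstance(model, OdeModel):
        raise ModelError("model builder did not return an OdeModel")

    if "compartments" in cfg:
        comps = {c["id"]: Compartment(c["id"], float(c["volume_litres"]))
                 for c in cfg["compartments"]}
        model = model.replace(compartments=comps)
    if "species" in cfg:
        by_name = {s["name"]: s for s in cfg["species"]}
        unknown_sp = set(by_name) - set(model.species_names)
        if unknown_sp:
            raise ModelError(f"species overrides for unknown names {sorted(unknown_sp)}")
        new_species = []
        for sp in model.species:
            ov = by_name.get(sp.name)
            if ov is None:
                new_species.append(sp)
            else:
                new_species.append(Species(
                    sp.name,
                    ov.get("compartment", sp.compartment),
                    ov.get("unit", sp.unit_kind),
                ))
        model = model.replace(species=new_species)
    if "initial_state" in cfg:
        model = model.replace(initial_state=[float(v) for v in cfg["initial_state"]])
    if "name" in cfg:
        model = model.replace(name=str(cfg["name"]))
    return model


def load_model_file(path: str | Path) -> OdeModel:
    """Load a declarative model file (JSON or YAML by extension)."""
    return build_model_from_config(_read_config(path))


# ---------------------------------------------------------------------------
# corpus directory format: one model file per model + a JSON manifest
# ---------------------------------------------------------------------------

def save_corpus(corpus: Corpus, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for meta in corpus.metadata:
        fname = f"{meta['model_id']}.json"
        cfg = {"name": meta["model_id"], "family": meta["family"],
               "params": meta["params"]}
        (directory / fname).write_text(json.dumps(cfg, indent=2))
        entries.append({**{k: meta[k] for k in
                           ("model_id", "family", "seed_offset", "n_species")},
                        "file": fname})
    manifest = {
        "format_version": 1,
        "spec": {
            "n_models": corpus.spec.n_models,
            "seed": corpus.spec.seed,
            "family_mix": corpus.spec.family_mix,
            "low_copy_scale_range": list(corpus.spec.low_copy_scale_range),
            "high_copy_scale_range": list(corpus.spec.high_copy_scale_range),
            "presim_horizon": corpus.spec.presim_horizon,
        },
        "models": entries,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_corpus_manifest(directory: str | Path) -> Corpus:
    """Rebuild a corpus from a saved directory (models via the registry)."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    spec_d = manifest["spec"]
    spec = CorpusSpec(
        n_models=spec_d["n_models"],
        seed=spec_d["seed"],
        family_mix=spec_d["family_mix"],
        low_copy_scale_range=tuple(spec_d["low_copy_scale_range"]),
        high_copy_scale_range=tuple(spec_d["high_copy_scale_range"]),
        presim_horizon=spec_d["presim_horizon"],
    )
    models = []
    metadata = []
    for entry in manifest["models"]:
        cfg = json.loads((directory / entry["file"]).read_text())
        models.append(build_model_from_config(cfg))
        metadata.append({**{k: entry[k] for k in
                            ("model_id", "family", "seed_offset", "n_species")},
                         "params": cfg["params"]})
    return Corpus(models=models, metadata=metadata, spec=spec)


def regenerate_corpus_from_manifest(directory: str | Path) -> Corpus:
    """Regenerate from the stored spec (bitwise-identical by seeding)."""
    return generate_corpus(load_corpus_manifest(directory).spec)
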