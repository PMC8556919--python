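"""Shared fixtures: small synthetic libraries and one session-scoped trained model."""

from __future__ import annotations

import numpy as np
import pytest

import specsim.binning as binning_mod
from specsim.binning import bin_spectrum, filter_peaks, fit_binning, normalize_and_transform
from specsim.labels import MolecularFingerprint, build_label_matrix_from_fingerprints
from specsim.model import ModelConfig, SiameseModel, split_by_compound, train
from specsim.pairs import GeneratorConfig
from specsim.spectra_io import Spectrum, select_annotated_positive
from specsim.synthetic import (
    SyntheticConfig,
    fingerprints_of,
    generate_compounds,
    generate_spectra,
)


def make_spectrum(
    mz,
    intensities,
    identifier="s0",
    inchikey="AAAAAAAAAAAAAA-BBBBBBBBBB-N",
    smiles="CCO",
    ionmode="positive",
):
    return Spectrum(
        identifier=identifier,
        mz=np.asarray(mz, dtype=float),
        intensities=np.asarray(intensities, dtype=float),
        smiles=smiles,
        inchikey=inchikey,
        ionmode=ionmode,
    )


def prepare_binned(spectra, scheme):
    return [bin_spectrum(normalize_and_transform(filter_peaks(s)), scheme) for s in spectra]


@pytest.fixture(scope="session")
def tiny_library():
    """10 clusters x 2 compounds x 3 spectra, binned on a 500-bin grid."""
    cfg = SyntheticConfig(
        n_clusters=10, members_per_cluster=2, spectra_per_compound=3,
        fp_bits=128, bit_density=0.15, mutation_rate=0.05,
        intensity_noise_sd=0.05, n_noise_peaks=2, seed=42,
    )
    compounds = generate_compounds(cfg)
    spectra = select_annotated_positive(generate_spectra(compounds, cfg))
    labels = build_label_matrix_from_fingerprints(fingerprints_of(compounds))
    prepared = [normalize_and_transform(filter_peaks(s)) for s in spectra]
    scheme = fit_binning(prepared, n_bins_total=500)
    binned = [bin_spectrum(s, scheme) for s in prepared]
    return {
        "cfg": cfg,
        "compounds": compounds,
        "spectra": spectra,
        "labels": labels,
        "scheme": scheme,
        "binned": binned,
    }


# -- the miniature trained model shared by the heavier acceptance tests -----

MINI_SYNTH = dict(
    n_clusters=30, members_per_cluster=5, spectra_per_compound=3,
    fp_bits=256, bit_density=0.2, mutation_rate=0.02,
    intensity_noise_sd=0.05, n_noise_peaks=2, seed=11,
)
MINI_MODEL = dict(
    hidden_dims=[64, 64], embedding_dim=32, dropout_rate=0.1,
    max_epochs=80, early_stop_patience=20, seed=0,
)
MINI_GEN = dict(batch_size=32, augmentation_enabled=True, cycles_per_epoch=24)


@pytest.fixture(scope="session")
def mini_experiment():
    """150 compounds x 3 spectra on a 1000-bin grid, split by compound."""
    cfg = SyntheticConfig(**MINI_SYNTH)
    compounds = generate_compounds(cfg)
    spectra = select_annotated_positive(generate_spectra(compounds, cfg))
    labels = build_label_matrix_from_fingerprints(fingerprints_of(compounds))
    prepared = [normalize_and_transform(filter_peaks(s)) for s in spectra]
    scheme = fit_binning(prepared, n_bins_total=1000)
    binned = [bin_spectrum(s, scheme) for s in prepared]
    keys = sorted({b.compound_key for b in binned})
    train_keys, val_keys, test_keys = split_by_compound(keys, 15, 20, seed=5)
    subsets = {
        name: [b for b in binned if b.compound_key in set(key_set)]
        for name, key_set in (("train", train_keys), ("val", val_keys), ("test", test_keys))
    }
    return {"labels": labels, "scheme": scheme, "binned": binned, "subsets": subsets}


@pytest.fixture(scope="session")
def trained_mini_model(mini_experiment):
    """The miniature model of the learnability criterion, trained once per session."""
    scheme = mini_experiment["scheme"]
    cfg = ModelConfig(input_dim=scheme.n_known, **MINI_MODEL)
    model = SiameseModel(cfg, scheme, label_metadata={"fp_type": "synthetic", "metric": "tanimoto"})
    train(
        model,
        mini_experiment["subsets"]["train"],
        mini_experiment["subsets"]["val"],
        mini_experiment["labels"],
        GeneratorConfig(**MINI_GEN),
    )
    return model
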