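"""Shared fixtures: small phantoms and (session-scoped) trained models."""

from __future__ import annotations

import numpy as np
import pytest

from octplaque.phantom import Lesion, PhantomSpec, generate_pullback


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """One mid-pullback lesion plus a guidewire wedge, 64×64 frames."""
    return PhantomSpec(
        n_frames=24,
        n_alines=64,
        n_radial=64,
        lesion_list=[Lesion(6, 17, 20, 8, 3, 10)],
        guidewire_center_aline=50,
        guidewire_width_alines=6,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_pullback(small_spec)


@pytest.fixture(scope="session")
def study_artifacts():
    """Scaled-down two-step study: data, trained models, evaluations.

    Session-scoped because training dominates the suite's runtime; the
    end-to-end acceptance checks and the pipeline tests share it.
    """
    from octplaque.experiments import (
        evaluate_study,
        run_two_step_study,
        study_pullbacks,
        train_study_models,
    )

    seed = 11
    data = study_pullbacks(seed)
    models = train_study_models(data, seed)
    two_step = evaluate_study(data, models)
    one = train_study_models(data, seed, one_step=True)
    one_step = evaluate_study(data, one, one_step=True)
    return {
        "seed": seed,
        "data": data,
        "models": models,
        "two_step": two_step,
        "one_step": one_step,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
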