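import numpy as np
import pytest

from mammodensity.density_core import compute_density
from mammodensity.phantom import PhantomSpec, generate_phantom
from mammodensity.segmentation import build_envelope, peel_subcutaneous_fat


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = int((a | b).sum())
    return 1.0 if union == 0 else int((a & b).sum()) / union


def make_battery(n_seeds: int = 50, master_seed: int = 12345):
    """Deterministic phantom battery with uniform true densities."""
    rng = np.random.default_rng(master_seed)
    battery = []
    for seed in range(n_seeds):
        spec = PhantomSpec(
            true_density=float(rng.uniform(0.0, 1.0)),
            seed=seed,
            laterality="L" if seed % 2 == 0 else "R",
            with_text_overlay=(seed % 3 == 0),
        )
        image, truth = generate_phantom(spec)
        battery.append((spec, image, truth))
    return battery


def eroded_truth_envelope(truth, laterality: str, margin: int) -> np.ndarray:
    """Ground-truth envelope with its skin line peeled by ``margin``."""
    env = truth.envelope_mask
    if laterality == "R":
        env = env[:, ::-1]
    env = peel_subcutaneous_fat(env, margin)
    return env[:, ::-1] if laterality == "R" else env


@pytest.fixture(scope="session")
def phantom_battery():
    return make_battery()


@pytest.fixture(scope="session")
def battery_results(phantom_battery):
    """(spec, image, truth, masks, density_result) for every battery seed."""
    results = []
    for spec, image, truth in phantom_battery:
        masks = build_envelope(image)
        results.append((spec, image, truth, masks,
                        compute_density(image, masks)))
    return results
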