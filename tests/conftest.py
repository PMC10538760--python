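import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def digit_batch():
    """Small labelled digit batch shared across tests."""
    from wakesleep.synthetic_data import generate_digits
    return generate_digits(256, size=16, n_classes=5, seed=0)


@pytest.fixture(scope="session")
def toy_protocol():
    """Shared 5-seed toy-experiment run (adversarial + baseline from a
    shared initialization), reused by the replication and covariance
    acceptance checks."""
    from wakesleep import toy_network as toy

    results = []
    seed_rng = np.random.default_rng(1)
    for _ in range(5):
        init_seed = int(seed_rng.integers(2 ** 31))
        params = toy.default_toy_params(student_seed=init_seed, w_bc=1.0)
        teacher = toy.simulate_population(params, "teacher", 40000,
                                          seed=init_seed + 1)
        student0 = toy.simulate_population(params, "student", 40000,
                                           seed=init_seed + 2)
        kl_init = toy.hexbin_kl(student0, teacher)
        adv, _, _ = toy.train_adversarial(params, steps=2000, seed=init_seed)
        base, _ = toy.train_baseline(params, steps=5000, seed=init_seed)
        student_adv = toy.simulate_population(adv, "student", 40000,
                                              seed=init_seed + 2)
        student_base = toy.simulate_population(base, "student", 40000,
                                               seed=init_seed + 2)
        cov_t = toy.analytic_covariance(params, "teacher")
        results.append({
            "params": params, "adv": adv, "base": base,
            "kl_init": kl_init,
            "kl_adv": toy.hexbin_kl(student_adv, teacher),
            "kl_base": toy.hexbin_kl(student_base, teacher),
            "frob_init": np.linalg.norm(
                toy.analytic_covariance(params, "student") - cov_t),
            "frob_adv": np.linalg.norm(
                toy.analytic_covariance(adv, "student") - cov_t),
        })
    return results
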