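import pytest

from cpf1screen import SimConfig, log2_fold_change, simulate_screen


@pytest.fixture(scope="session")
def strong_multi_screen():
    """Multiplexed screen with near-saturating guide activity and strong dropout."""
    cfg = SimConfig(
        n_essential=120, n_nonessential=120, guides_per_gene=3,
        mode="cpf1_multi", p_active_guide=0.9, essential_lfc_mean=-1.5,
        essential_lfc_sd=0.3, timepoints=(1, 2, 3, 4), replicates=3,
        depth_mean=500.0, seed=11,
    )
    lib, cm, refs, truth = simulate_screen(cfg)
    return cfg, lib, cm, refs, truth


@pytest.fixture(scope="session")
def strong_multi_fc(strong_multi_screen):
    _, _, cm, _, _ = strong_multi_screen
    return log2_fold_change(cm)


@pytest.fixture(scope="session")
def mono_motif_screen():
    """Mono-cistronic screen whose guide activity follows the planted motif."""
    cfg = SimConfig(
        n_essential=200, n_nonessential=100, guides_per_gene=3,
        mode="cpf1_mono", p_active_guide=0.45, essential_lfc_mean=-1.5,
        essential_lfc_sd=0.2, timepoints=(2, 4), replicates=3,
        depth_mean=500.0, motif_effect=1.0, seed=7,
    )
    lib, cm, refs, truth = simulate_screen(cfg)
    return cfg, lib, cm, refs, truth
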