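import pytest

import blindsim as bs


@pytest.fixture(scope="session")
def star128():
    """Default Siemens star: 128 px, FOV 13 d_PSF, 20 lobes."""
    return bs.make_siemens_star(128)


@pytest.fixture(scope="session")
def psf8():
    """Airy PSF with FWHM 8 px (default grid sampling of one d_PSF)."""
    return bs.airy_psf(8.0)


@pytest.fixture(scope="session")
def small_psf():
    """Compact Airy PSF for small-frame tests."""
    return bs.airy_psf(2.0, support=8)


@pytest.fixture(scope="session")
def star_acquisition(star128):
    """Scaled star acquisition: N=16 frames at eta = 2.5 on a 128 px star."""
    d_psf = 128 / 13.0
    d_sp = d_psf / 2.5
    psf = bs.airy_psf(d_psf)
    stack = bs.speckle_stack(bs.SpeckleParams(d_sp=d_sp, seed=11), 16, star128.shape)
    lr = bs.blur(bs.illuminate(star128, stack), psf)
    hp = bs.hp_extract(lr)
    return {
        "star": star128,
        "psf": psf,
        "d_psf": d_psf,
        "d_sp": d_sp,
        "stack": stack,
        "lr": lr,
        "hp": hp,
    }
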