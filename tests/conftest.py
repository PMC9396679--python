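import pytest

from octapipe import AcquisitionMeta
from octapipe.flattening import applied_shifts, flatten_volume
from octapipe.phantom import generate_structural, species_preset
from octapipe.reconstruction import to_log_grayscale
from octapipe.registration import average_bm_volume, axial_align_volume


def small_meta(n_lat=60, n_repeats=3, n_depth=512):
    return AcquisitionMeta(
        n_locations=n_lat,
        n_repeats=n_repeats,
        n_ascans=n_lat,
        n_depth=n_depth,
        n_k=2 * n_depth,
    )


@pytest.fixture(scope="session")
def mouse_bundle():
    """One mouse phantom processed through registration and flattening,
    with truth surfaces mapped into the flattened frame."""
    meta = small_meta(60)
    spec = species_preset("mouse", meta=meta, seed=11)
    vol, truth = generate_structural(spec)
    log = to_log_grayscale(vol)
    avg = average_bm_volume(log)
    aligned, offsets = axial_align_volume(avg)
    flat, surface = flatten_volume(aligned)
    center = meta.n_depth // 3
    shifts = applied_shifts(surface.z, center)
    resid = truth.jitter_px + offsets  # leftover global jitter per location
    truth_ilm_flat = truth.ilm_surface.z + resid[:, None] + shifts
    truth_rpe_flat = truth.rpe_surface.z + resid[:, None] + shifts
    return {
        "meta": meta,
        "spec": spec,
        "vol": vol,
        "truth": truth,
        "log": log,
        "aligned": aligned,
        "offsets": offsets,
        "flat": flat,
        "surface": surface,
        "center": center,
        "truth_ilm_flat": truth_ilm_flat,
        "truth_rpe_flat": truth_rpe_flat,
    }
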