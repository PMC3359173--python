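import json
from pathlib import Path

import numpy as np
import pytest

from cellfiler import (
    DetectorParams,
    detect_walls,
    fit_spline,
    make_fixture_suite,
    read_image,
    read_polyline,
    sample_intensity,
)

# detector settings used throughout the synthetic-image tests: window spans
# the rendered ridge, floor sits well above background noise (sd 10) and
# well below ridge peaks (1000)
FIXTURE_PARAMS = DetectorParams(window=9, stringency=1.5, min_intensity=100.0)


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory) -> Path:
    """Synthetic ground-truthed image suite, generated once per session."""
    out = tmp_path_factory.mktemp("fixtures")
    make_fixture_suite(out, seed=0)
    return out


@pytest.fixture(scope="session")
def manifest(fixture_suite):
    with open(fixture_suite / "manifest.json", encoding="utf-8") as fh:
        return json.load(fh)


def load_case(fixture_dir: Path, manifest: dict, name: str):
    """(image, polyline, truth dict) for one fixture case."""
    case = manifest["cases"][name]
    image = read_image(fixture_dir / case["image"])
    poly = read_polyline(fixture_dir / case["polyline"])
    with open(fixture_dir / case["truth"], encoding="utf-8") as fh:
        truth = json.load(fh)
    return image, poly, truth


def run_detection(image, poly, params=FIXTURE_PARAMS, step_px=1.0):
    """Profile + wall detection for one case; returns (path, profile, wallset)."""
    path = fit_spline(poly, step_px=step_px)
    prof = sample_intensity(image, path)
    return path, prof, detect_walls(prof, params, path=path)


def match_walls(detected_s_um: np.ndarray, true_s_um: np.ndarray, tol_um: float):
    """Greedy one-to-one matching of detected to true wall positions.

    Returns (n_matched, errors of matched pairs); recall = n_matched /
    n_true, precision = n_matched / n_detected.
    """
    detected = list(detected_s_um)
    errors = []
    n_matched = 0
    for t in true_s_um:
        if not detected:
            break
        diffs = [abs(d - t) for d in detected]
        i = int(np.argmin(diffs))
        if diffs[i] <= tol_um:
            errors.append(diffs[i])
            n_matched += 1
            detected.pop(i)
    return n_matched, np.asarray(errors)
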