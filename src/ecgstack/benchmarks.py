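"""Published benchmark confusion matrices for the four-class heartbeat task.

These 4x4 matrices (rows = true N,S,V,F; columns = predicted n,s,v,f) are the
printed single-feature and feature-combination KNN results on the standard
arrhythmia benchmark. They serve as fixed inputs for golden tests of the
metric calculus and for the acceptance report; they are not produced by this
package.
"""
from __future__ import annotations

import numpy as np

from .evaluate import ConfusionMatrix

# Single-feature KNN models
KNN_MORPH = ConfusionMatrix(np.array([
    [9009, 12, 12, 2],
    [40, 271, 1, 0],
    [23, 0, 690, 3],
    [12, 1, 8, 57],
]))

KNN_INTER = ConfusionMatrix(np.array([
    [8939, 26, 56, 14],
    [135, 169, 8, 0],
    [162, 5, 544, 5],
    [47, 0, 7, 24],
]))

KNN_AMP = ConfusionMatrix(np.array([
    [8960, 20, 53, 2],
    [306, 6, 0, 0],
    [527, 3, 186, 0],
    [68, 0, 9, 1],
]))

# Feature-combination KNN models
KNN_MORPH_INTER = ConfusionMatrix(np.array([
    [9010, 12, 11, 2],
    [42, 269, 1, 0],
    [22, 2, 691, 1],
    [15, 0, 7, 56],
]))

KNN_MORPH_AMP = ConfusionMatrix(np.array([
    [9010, 12, 11, 2],
    [40, 271, 1, 0],
    [23, 0, 690, 3],
    [12, 1, 8, 57],
]))

KNN_INTER_AMP = ConfusionMatrix(np.array([
    [8942, 27, 54, 12],
    [77, 224, 11, 0],
    [85, 8, 619, 4],
    [28, 0, 9, 41],
]))

KNN_MORPH_INTER_AMP = ConfusionMatrix(np.array([
    [9009, 13, 11, 2],
    [37, 274, 1, 0],
    [22, 2, 691, 1],
    [15, 0, 7, 56],
]))

SINGLE_FEATURE = {
    "morph": KNN_MORPH,
    "inter": KNN_INTER,
    "amp": KNN_AMP,
}

COMBINATIONS = {
    "morph+inter": KNN_MORPH_INTER,
    "morph+amp": KNN_MORPH_AMP,
    "inter+amp": KNN_INTER_AMP,
    "morph+inter+amp": KNN_MORPH_INTER_AMP,
}
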