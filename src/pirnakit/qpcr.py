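"""qPCR arithmetic: ddCt fold changes, copy-number ratios, ChIP enrichment.

Ct tables are tidy DataFrames with columns (sample, target, replicate, Ct).
Amplification efficiency is fixed at 2 by default (no efficiency
correction), so one cycle is one doubling; fold change is E^(-ddCt).
Replicates are aggregated mean-first: mean Ct per (sample, target) feeds the
point estimate, while the SEM is propagated from replicate-level dCt values
(replicates paired by their replicate id for the target - reference
difference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["sample", "target", "replicate", "Ct"]
DEFAULT_REFERENCE_GENE = "rp49"


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (df["Ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df


def significance_stars(p: float) -> str:
    """Figure-legend convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class FoldChangeResult:
    fold: float
    sem: float
    ddct: float
    case: str
    control: str
    target: str


def _delta_ct(
    ct: pd.DataFrame, sample: str, target: str, reference_gene: str
) -> tuple[float, np.ndarray]:
    """(mean dCt, replicate-level dCt) for one sample."""
    sub = ct[ct["sample"] == sample]
    t = sub[sub["target"] == target].set_index("replicate")["Ct"]
    r = sub[sub["target"] == reference_gene].set_index("replicate")["Ct"]
    if len(r) == 0:
        raise ValueError(
            f"no {reference_gene!r} rows for sample {sample!r} (reference gene required)"
        )
    if len(t) == 0:
        raise ValueError(f"no {target!r} rows for sample {sample!r}")
    mean_dct = float(t.mean() - r.mean())
    common = t.index.intersection(r.index)
    reps = (t.loc[common] - r.loc[common]).to_numpy(dtype=float)
    if len(reps) == 0:  # unpaired replicate ids: fall back to the mean only
        reps = np.array([mean_dct])
    return mean_dct, reps


def ddct_fold(
    ct: pd.DataFrame,
    target: str,
    case: str,
    control: str,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    efficiency: float = 2.0,
) -> FoldChangeResult:
    """Relative expression of ``target`` in case vs control, E^(-ddCt).

    dCt = Ct_target - Ct_reference per sample (mean-first), ddCt =
    dCt_case - dCt_control. SEM combines the replicate-level dCt standard
    errors of both samples in quadrature and is mapped to the fold scale as
    fold * ln(E) * SEM(ddCt).
    """
    dct_case, reps_case = _delta_ct(ct, case, target, reference_gene)
    dct_ctrl, reps_ctrl = _delta_ct(ct, control, target, reference_gene)
    ddct = dct_case - dct_ctrl
    fold = efficiency ** (-ddct)

    def _sem(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0

    sem_ddct = math.hypot(_sem(reps_case), _sem(reps_ctrl))
    return FoldChangeResult(
        fold=float(fold),
        sem=float(fold * math.log(efficiency) * sem_ddct),
        ddct=float(ddct),
        case=case,
        control=control,
        target=target,
    )


def copy_number_ratio(
    ct: pd.DataFrame,
    element: str,
    strain_a: str,
    strain_b: str,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    efficiency: float = 2.0,
) -> FoldChangeResult:
    """Relative genomic copy number of ``element`` in strain_b vs strain_a.

    Identical ddCt arithmetic applied to Ct values measured on genomic DNA,
    normalized to a single-copy reference gene.
    """
    return ddct_fold(
        ct, element, case=strain_b, control=strain_a,
        reference_gene=reference_gene, efficiency=efficiency,
    )


@dataclass(frozen=True)
class ChipResult:
    percent_input: float
    percent_input_sem: float
    enrichment: float
    enrichment_sem: float
    target: str
    control_region: str
    replicate_enrichment: tuple[float, ...]


def percent_input(
    ct_ip: pd.DataFrame,
    ct_input: pd.DataFrame,
    sample: str,
    target: str,
    input_fraction: float,
    efficiency: float = 2.0,
) -> np.ndarray:
    """Replicate-level percent-input recovery at one region.

    %input = input_fraction_correction * E^(Ct_input - Ct_IP) * 100, with
    replicates paired by id. ``input_fraction`` is the correction for the
    fraction of chromatin set aside as input (no silent default: it depends
    on the experiment's dilution scheme).
    """
    ip = ct_ip[(ct_ip["sample"] == sample) & (ct_ip["target"] == target)]
    inp = ct_input[(ct_input["sample"] == sample) & (ct_input["target"] == target)]
    if len(ip) == 0 or len(inp) == 0:
        raise ValueError(f"missing IP or input rows for {sample!r}/{target!r}")
    ip_ct = ip.set_index("replicate")["Ct"]
    inp_ct = inp.set_index("replicate")["Ct"]
    common = ip_ct.index.intersection(inp_ct.index)
    if len(common) == 0:
        raise ValueError("no paired replicates between IP and input")
    return (
        input_fraction
        * efficiency ** (inp_ct.loc[common] - ip_ct.loc[common]).to_numpy(dtype=float)
        * 100.0
    )


def chip_enrichment(
    ct_ip: pd.DataFrame,
    ct_input: pd.DataFrame,
    sample: str,
    target: str,
    input_fraction: float,
    control_region: str = DEFAULT_REFERENCE_GENE,
    efficiency: float = 2.0,
) -> ChipResult:
    """Percent input at ``target`` and enrichment relative to the control
    region, with SEM over replicates."""
    pi_target = percent_input(ct_ip, ct_input, sample, target, input_fraction, efficiency)
    pi_control = percent_input(
        ct_ip, ct_input, sample, control_region, input_fraction, efficiency
    )
    n = min(len(pi_target), len(pi_control))
    rel = pi_target[:n] / pi_control[:n]

    def _sem(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0

    return ChipResult(
        percent_input=float(np.mean(pi_target)),
        percent_input_sem=_sem(pi_target),
        enrichment=float(np.mean(rel)),
        enrichment_sem=_sem(rel),
        target=target,
        control_region=control_region,
        replicate_enrichment=tuple(float(x) for x in rel),
    )


def compare_enrichment(
    result_a: ChipResult, result_b: ChipResult, welch: bool = False
) -> tuple[float, float, str]:
    """Unpaired two-sample t-test between genotypes on replicate-level
    enrichment; returns (t, p, stars). Equal-variance by default (the
    classic unpaired test), Welch by flag."""
    t, p = stats.ttest_ind(
        result_a.replicate_enrichment,
        result_b.replicate_enrichment,
        equal_var=not welch,
    )
    return float(t), float(p), significance_stars(float(p))
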