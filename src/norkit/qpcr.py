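"""rDNA copy-number estimation from qPCR Ct tables.

Relative quantification against a single-copy control amplicon: for each
target amplicon the relative quantity is (1+E_t)^(-Ct_t) / (1+E_c)^(-Ct_c),
normalized to a calibrator sample of known copy number. With perfect
efficiency (E = 1) this reduces to the familiar 2^-ddCt. The per-sample
estimate averages over the IGS target amplicons; the standard error is taken
over the (amplicon x replicate) estimates. The calibrator copy number is a
required user input — typically the diploid-genome average of a total
genomic DNA standard — not a built-in constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("sample", "amplicon", "ct")


@dataclass
class QPCRTable:
    """Ct measurements plus per-amplicon efficiencies and calibrator info.

    ``data`` has one row per well: sample, amplicon, ct (replicates are
    repeated rows). ``control`` names the single-copy control amplicon;
    every sample must have control rows. Efficiencies are in (0, 1].
    """

    data: pd.DataFrame
    control: str
    calibrator: str
    calibrator_copies: float
    efficiency: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table missing columns {missing}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("all Ct values must be positive")
        for a, e in self.efficiency.items():
            if not 0.0 < e <= 1.0:
                raise ValueError(f"efficiency for {a!r} must be in (0,1], got {e}")
        samples = set(self.data["sample"])
        if self.calibrator not in samples:
            raise ValueError(f"calibrator sample {self.calibrator!r} not in table")
        have_control = set(self.data.loc[self.data["amplicon"] == self.control, "sample"])
        lacking = samples - have_control
        if lacking:
            raise ValueError(f"samples without control amplicon rows: {sorted(lacking)}")

    def eff(self, amplicon: str) -> float:
        return self.efficiency.get(amplicon, 1.0)

    @classmethod
    def from_tsv(
        cls, path, control: str, calibrator: str, calibrator_copies: float,
        efficiency: dict[str, float] | None = None,
    ) -> "QPCRTable":
        return cls(pd.read_csv(path, sep="\t"), control, calibrator,
                   calibrator_copies, efficiency or {})


def estimate_copies(table: QPCRTable) -> pd.DataFrame:
    """Per-sample copy-number estimates with standard errors.

    Returns a DataFrame (sample, copies, se, n) where n counts the
    (amplicon x replicate) estimates entering the mean.
    """
    df = table.data
    targets = sorted(set(df["amplicon"]) - {table.control})
    if not targets:
        raise ValueError("no target amplicons besides the control")

    ctrl_mean = df[df["amplicon"] == table.control].groupby("sample")["ct"].mean()

    def rel_quantity(sample: str, amplicon: str, ct: float) -> float:
        e_t, e_c = table.eff(amplicon), table.eff(table.control)
        return (1 + e_t) ** (-ct) / (1 + e_c) ** (-float(ctrl_mean[sample]))

    # calibrator relative quantity per amplicon (replicate-mean Ct)
    cal = df[(df["sample"] == table.calibrator) & (df["amplicon"] != table.control)]
    cal_rq = {
        a: rel_quantity(table.calibrator, a, float(g["ct"].mean()))
        for a, g in cal.groupby("amplicon")
    }
    rows = []
    for sample, g in df[df["amplicon"] != table.control].groupby("sample"):
        ests = []
        for _, row in g.iterrows():
            a = row["amplicon"]
            if a not in cal_rq:
                raise ValueError(f"calibrator lacks amplicon {a!r}")
            ests.append(
                rel_quantity(sample, a, row["ct"]) / cal_rq[a] * table.calibrator_copies
            )
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests)) if len(ests) > 1 else 0.0
        rows.append({"sample": sample, "copies": ests.mean(), "se": se, "n": len(ests)})
    return pd.DataFrame(rows).sort_values("sample").reset_index(drop=True)


def simulate_ct_table(
    true_copies: dict[str, float],
    calibrator: str,
    calibrator_copies: float,
    n_target_amplicons: int = 4,
    n_replicates: int = 3,
    ct_sd: float = 0.2,
    efficiency: float = 1.0,
    control: str = "control",
    seed: int | np.random.Generator = 0,
    noise_scope: str = "all",
) -> QPCRTable:
    """Generate a synthetic Ct table by inverting the quantification model.

    Each sample's target Ct is set so that the relative quantity equals its
    true copy number (per calibrator copy), then Gaussian noise of sd
    ``ct_sd`` cycles is added per well. ``noise_scope`` is ``'all'`` (every
    well noisy — realistic, but control/calibrator noise propagates into the
    estimate) or ``'sample_targets'`` (noise only on the test samples'
    target wells; the reference wells are treated as exact).
    """
    if noise_scope not in ("all", "sample_targets"):
        raise ValueError(f"unknown noise_scope {noise_scope!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base_ct = 24.0
    rows = []
    samples = dict(true_copies)
    samples.setdefault(calibrator, calibrator_copies)
    for sample, copies in samples.items():
        for rep in range(n_replicates):
            noisy = noise_scope == "all"
            rows.append(
                {"sample": sample, "amplicon": control,
                 "ct": base_ct + (rng.normal(0, ct_sd) if noisy else 0.0)}
            )
        for a in range(n_target_amplicons):
            # Ct_t = Ct_c - log_{1+E}(copies / calibrator_copies) puts the
            # calibrator's target Ct at base_ct
            ct_t = base_ct - np.log(copies / calibrator_copies) / np.log(1 + efficiency)
            noisy = noise_scope == "all" or sample != calibrator
            for rep in range(n_replicates):
                rows.append(
                    {"sample": sample, "amplicon": f"IGS_{a+1}",
                     "ct": ct_t + (rng.normal(0, ct_sd) if noisy else 0.0)}
                )
    eff = {f"IGS_{a+1}": efficiency for a in range(n_target_amplicons)}
    eff[control] = efficiency
    return QPCRTable(pd.DataFrame(rows), control, calibrator, calibrator_copies, eff)
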