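# Packaged guideline-flavored rule set for the larynx treatment model.
#
# This is a documented elicitation in the spirit of consensus head-and-neck
# guidelines (NCCN-like), NOT a transcription of any published table: apart
# from the two anchor probabilities (priority 10), all values are the
# package's own reconstruction and are meant to be edited by modelers.
#
# Resolution: highest priority wins; among equal priorities the rule listed
# last wins (a warning is logged if their probabilities differ); cells
# matched by no rule fall back to the per-treatment defaults below, which
# encode "uncertain" (0.5) recommendations for unclear staging such as
# TX / T0 / TIS.
#
# Priorities used here:
#   10  printed anchor probabilities (must not be overridden)
#    5  hard prerequisite: chemotherapy intolerance suppresses systemic therapy
#    4  distant metastasis (M1): palliative intent, systemic options elevated
#    3  T4b: technically unresectable primary
#    2  stage groups (early N0 / early node-positive / locally advanced)

defaults:
  larynx_surgery: 0.5
  radiotherapy: 0.5
  radiochemotherapy: 0.5
  chemotherapy: 0.5
  immunotherapy: 0.5

rules:
  # --- stage groups (M0 or MX, i.e. no known distant metastasis) ---------
  - {name: early-n0-surgery,        t: [T1, T1a, T1b, T2], n: [N0], m: [MX, M0], tolerance: any, treatment: larynx_surgery,    p_true: 0.90, priority: 2}
  - {name: early-n0-radiotherapy,   t: [T1, T1a, T1b, T2], n: [N0], m: [MX, M0], tolerance: any, treatment: radiotherapy,      p_true: 0.85, priority: 2}
  - {name: early-n0-radiochemo,     t: [T1, T1a, T1b, T2], n: [N0], m: [MX, M0], tolerance: any, treatment: radiochemotherapy, p_true: 0.10, priority: 2}
  - {name: early-n0-chemo,          t: [T1, T1a, T1b, T2], n: [N0], m: [MX, M0], tolerance: any, treatment: chemotherapy,      p_true: 0.05, priority: 2}
  - {name: early-n0-immuno,         t: [T1, T1a, T1b, T2], n: [N0], m: [MX, M0], tolerance: any, treatment: immunotherapy,     p_true: 0.02, priority: 2}

  - {name: early-nplus-surgery,     t: [T1, T1a, T1b, T2], n: [N1, N2a, N2b, N2c, N3a, N3b], m: [MX, M0], tolerance: any, treatment: larynx_surgery,    p_true: 0.70, priority: 2}
  - {name: early-nplus-radiotherapy, t: [T1, T1a, T1b, T2], n: [N1, N2a, N2b, N2c, N3a, N3b], m: [MX, M0], tolerance: any, treatment: radiotherapy,     p_true: 0.45, priority: 2}
  - {name: early-nplus-radiochemo,  t: [T1, T1a, T1b, T2], n: [N1, N2a, N2b, N2c, N3a, N3b], m: [MX, M0], tolerance: any, treatment: radiochemotherapy, p_true: 0.70, priority: 2}
  - {name: early-nplus-chemo,       t: [T1, T1a, T1b, T2], n: [N1, N2a, N2b, N2c, N3a, N3b], m: [MX, M0], tolerance: any, treatment: chemotherapy,      p_true: 0.35, priority: 2}
  - {name: early-nplus-immuno,      t: [T1, T1a, T1b, T2], n: [N1, N2a, N2b, N2c, N3a, N3b], m: [MX, M0], tolerance: any, treatment: immunotherapy,     p_true: 0.05, priority: 2}

  - {name: advanced-surgery,        t: [T3, T4a], n: any, m: [MX, M0], tolerance: any, treatment: larynx_surgery,    p_true: 0.75, priority: 2}
  - {name: advanced-radiotherapy,   t: [T3, T4a], n: any, m: [MX, M0], tolerance: any, treatment: radiotherapy,      p_true: 0.35, priority: 2}
  - {name: advanced-radiochemo,     t: [T3, T4a], n: any, m: [MX, M0], tolerance: any, treatment: radiochemotherapy, p_true: 0.80, priority: 2}
  - {name: advanced-chemo,          t: [T3, T4a], n: any, m: [MX, M0], tolerance: any, treatment: chemotherapy,      p_true: 0.30, priority: 2}
  - {name: advanced-immuno,         t: [T3, T4a], n: any, m: [MX, M0], tolerance: any, treatment: immunotherapy,     p_true: 0.05, priority: 2}

  # --- unresectable primary (T4b) ----------------------------------------
  - {name: t4b-surgery,             t: [T4b], n: any, m: any, tolerance: any, treatment: larynx_surgery,    p_true: 0.10, priority: 3}
  - {name: t4b-radiotherapy,        t: [T4b], n: any, m: any, tolerance: any, treatment: radiotherapy,      p_true: 0.35, priority: 3}
  - {name: t4b-radiochemo,          t: [T4b], n: any, m: any, tolerance: any, treatment: radiochemotherapy, p_true: 0.75, priority: 3}
  - {name: t4b-chemo,               t: [T4b], n: any, m: any, tolerance: any, treatment: chemotherapy,      p_true: 0.60, priority: 3}
  - {name: t4b-immuno,              t: [T4b], n: any, m: any, tolerance: any, treatment: immunotherapy,     p_true: 0.40, priority: 3}

  # --- distant metastasis (M1) -------------------------------------------
  - {name: m1-surgery,              t: any, n: any, m: [M1], tolerance: any, treatment: larynx_surgery,    p_true: 0.15, priority: 4}
  - {name: m1-radiotherapy,         t: any, n: any, m: [M1], tolerance: any, treatment: radiotherapy,      p_true: 0.25, priority: 4}
  - {name: m1-radiochemo,           t: any, n: any, m: [M1], tolerance: any, treatment: radiochemotherapy, p_true: 0.30, priority: 4}
  - {name: m1-chemo,                t: any, n: any, m: [M1], tolerance: any, treatment: chemotherapy,      p_true: 0.85, priority: 4}
  - {name: m1-immuno,               t: any, n: any, m: [M1], tolerance: any, treatment: immunotherapy,     p_true: 0.60, priority: 4}

  # --- hard prerequisite: chemotherapy intolerance ------------------------
  - {name: intolerant-chemo,        t: any, n: any, m: any, tolerance: intolerant, treatment: chemotherapy,      p_true: 0.02, priority: 5}
  - {name: intolerant-radiochemo,   t: any, n: any, m: any, tolerance: intolerant, treatment: radiochemotherapy, p_true: 0.02, priority: 5}

  # --- printed anchor probabilities ---------------------------------------
  - {name: anchor-t2n2a-m0-surgery, t: [T2], n: [N2a], m: [M0], tolerance: tolerant, treatment: larynx_surgery, p_true: 0.74, priority: 10}
  - {name: anchor-t2n2a-m1-surgery, t: [T2], n: [N2a], m: [M1], tolerance: tolerant, treatment: larynx_surgery, p_true: 0.17, priority: 10}
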