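"""Reference evaluation counts from the published colonoscopy case study.

These printed counts are inputs to the evaluation machinery: per-degree
video/relevance tallies for the threshold curve, per-term coded-sample
tallies for the recall report, exclusion tallies, and the batch summary
numerators/denominators for four focal terms.
"""

# (total_degree, n_videos, n_relevant) for each observed degree, descending
TABLE_DEGREE_COUNTS = [
    (44, 1, 1), (41, 1, 1), (26, 1, 1), (23, 1, 1), (22, 1, 1), (21, 1, 1),
    (20, 2, 2), (19, 1, 1), (18, 1, 1), (17, 2, 2), (16, 1, 1), (15, 2, 2),
    (14, 1, 1), (13, 1, 1), (12, 2, 2), (11, 2, 2), (10, 1, 1), (9, 1, 1),
    (7, 2, 1), (6, 1, 1), (5, 2, 0), (4, 2, 2), (3, 2, 1), (2, 5, 1),
    (1, 5, 1), (0, 71, 7),
]

# expected cumulative cells per degree row:
# degree -> (cum_videos, cum_relevant, precision_pct, recall_pct, f1_pct)
TABLE_CURVE_EXPECTED = {
    44: (1, 1, 100, 2.7, 5.3),
    41: (2, 2, 100, 5.4, 10.3),
    26: (3, 3, 100, 8.1, 15.0),
    23: (4, 4, 100, 10.8, 19.5),
    22: (5, 5, 100, 13.5, 23.8),
    21: (6, 6, 100, 16.2, 27.9),
    20: (8, 8, 100, 21.6, 35.6),
    19: (9, 9, 100, 24.3, 39.1),
    18: (10, 10, 100, 27.0, 42.6),
    17: (12, 12, 100, 32.4, 49.0),
    16: (13, 13, 100, 35.1, 52.0),
    15: (15, 15, 100, 40.5, 57.7),
    14: (16, 16, 100, 43.2, 60.4),
    13: (17, 17, 100, 45.9, 63.0),
    12: (19, 19, 100, 51.4, 67.9),
    11: (21, 21, 100, 56.8, 72.4),
    10: (22, 22, 100, 59.5, 74.6),
    9: (23, 23, 100, 62.2, 76.7),
    7: (25, 24, 96, 64.9, 77.4),
    6: (26, 25, 96, 67.6, 79.4),
    5: (28, 25, 89, 67.6, 76.9),
    4: (30, 27, 90, 73.0, 80.6),
    3: (32, 28, 88, 75.7, 81.2),
    2: (37, 29, 78, 78.4, 78.4),
    1: (42, 30, 71, 81.1, 75.9),
    0: (113, 37, 33, 100.0, 49.3),
}

# per-expansion-term coded-sample tallies:
# term -> (n_coded, n_relevant, n_relevant_mentioning_focal)
TABLE_RECALL_COUNTS = {
    "suprep": (25, 18, 9),
    "peg": (25, 1, 0),
    "sutab": (25, 4, 4),
    "plenvu": (25, 23, 15),
    "glycol": (25, 0, 0),
    "miralax": (25, 5, 2),
}

# exclusion tallies for the 150-video coded sample
N_CODED = 150
N_NON_ENGLISH = 28
N_DUPLICATE = 8
N_MISSING = 1
N_RETAINED = 113

# batch summary: focal term -> (n_coded, set_A_relevant, set_B_degree_ge_1,
#                               A_and_B, expected precision %, expected recall %)
TABLE_SUMMARY = {
    "colonoscopy": (150, 37, 42, 30, 71, 81),
    "fobt": (125, 50, 33, 27, 82, 54),
    "mammogram": (250, 77, 28, 23, 82, 30),
    "pap test": (250, 87, 65, 59, 91, 68),
}


def degree_fixture():
    """Degree records + relevance map realizing TABLE_DEGREE_COUNTS."""
    from termscout.network_eval import DegreeRecord

    records, relevance = [], {}
    i = 0
    for deg, n, n_rel in TABLE_DEGREE_COUNTS:
        for j in range(n):
            vid = f"v{i:03d}"
            i += 1
            records.append(DegreeRecord(video_id=vid, indegree=deg, outdegree=0))
            relevance[vid] = j < n_rel
    return records, relevance
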