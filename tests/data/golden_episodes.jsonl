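{"tokens": [50, 17, 80, 50, 18, 80, 51, 17, 80, 48, 17, 80, 49, 22, 80, 51, 22, 80, 50, 19, 80, 49, 18, 80, 48, 19, 80, 50, 23, 80, 48, 21, 80, 48, 23, 80, 51, 16, 80, 49, 23, 80, 50, 22, 80, 48, 20, 80, 52, 20, 81, 54, 23, 81, 54, 19, 81, 52, 18, 81, 53, 16, 81, 55, 16, 81, 54, 16, 81, 53, 19, 81, 54, 22, 81, 53, 18, 81, 52, 22, 81, 54, 18, 81, 55, 23, 81, 55, 20, 81, 55, 19, 81, 55, 17, 81, 82, 48, 16], "positions": [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31, 32, 33, 34, 35, 36, 37, 38, 39, 40, 41, 42, 43, 44, 45, 46, 47, 48, 49, 50, 51, 52, 53, 54, 55, 56, 57, 58, 59, 60, 61, 62, 63, 64, 65, 66, 67, 68, 69, 70, 71, 72, 73, 74, 75, 76, 77, 78, 79, 80, 81, 82, 83, 84, 85, 86, 87, 88, 89, 90, 91, 92, 93, 94, 95, 96, 97, 98], "target": [80], "target_positions": [99], "context_len": 96, "example_spans": [[0, 3], [3, 6], [6, 9], [9, 12], [12, 15], [15, 18], [18, 21], [21, 24], [24, 27], [27, 30], [30, 33], [33, 36], [36, 39], [39, 42], [42, 45], [45, 48], [48, 51], [51, 54], [54, 57], [57, 60], [60, 63], [63, 66], [66, 69], [69, 72], [72, 75], [75, 78], [78, 81], [81, 84], [84, 87], [87, 90], [90, 93], [93, 96]], "example_groups": [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1], "query_group": 0, "split": "test_query", "family": "category"}
{"tokens": [2, 8, 11, 13, 1, 5, 17, 13, 1, 7, 16, 12, 1, 9, 15, 11, 1, 8, 14, 10, 1, 6, 18, 14, 0, 8, 10, 14, 4, 8, 12, 12, 3, 8, 13, 11, 19, 0, 5], "positions": [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31, 32, 33, 34, 35, 36, 37, 38], "target": [13, 17], "target_positions": [39, 40], "context_len": 36, "example_spans": [[0, 4], [4, 8], [8, 12], [12, 16], [16, 20], [20, 24], [24, 28], [28, 32], [32, 36]], "example_groups": [0, 1, 1, 1, 0, 1, 0, 0, 0], "query_group": 0, "split": "test_query", "family": "compositional"}
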