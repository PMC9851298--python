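# synthetic fixture background network: 300 edges over 120 invented gene symbols
gene_a	gene_b
SG0025	SG0058
SG0051	SG0049
SG0076	SG0071
SG0076	SG0038
SG0077	SG0017
SG0106	SG0031
SG0007	SG0042
SG0036	SG0071
SG0099	SG0076
SG0087	SG0108
SG0045	SG0066
SG0065	SG0020
SG0115	SG0084
SG0116	SG0003
SG0002	SG0049
SG0059	SG0114
SG0092	SG0028
SG0045	SG0072
SG0023	SG0013
SG0014	SG0021
SG0085	SG0019
SG0048	SG0088
SG0028	SG0097
SG0039	SG0022
SG0078	SG0111
SG0039	SG0042
SG0081	SG0021
SG0001	SG0014
SG0046	SG0073
SG0020	SG0071
SG0107	SG0089
SG0094	SG0033
SG0089	SG0075
SG0095	SG0082
SG0062	SG0119
SG0053	SG0107
SG0105	SG0041
SG0004	SG0082
SG0094	SG0040
SG0015	SG0035
SG0067	SG0119
SG0064	SG0092
SG0031	SG0009
SG0047	SG0000
SG0028	SG0059
SG0042	SG0114
SG0051	SG0030
SG0091	SG0006
SG0091	SG0078
SG0052	SG0012
SG0071	SG0007
SG0026	SG0002
SG0111	SG0014
SG0041	SG0110
SG0027	SG0061
SG0092	SG0020
SG0087	SG0067
SG0034	SG0007
SG0044	SG0056
SG0099	SG0004
SG0035	SG0022
SG0011	SG0085
SG0102	SG0078
SG0116	SG0104
SG0110	SG0046
SG0061	SG0080
SG0025	SG0099
SG0003	SG0083
SG0073	SG0085
SG0117	SG0034
SG0032	SG0099
SG0063	SG0068
SG0075	SG0099
SG0026	SG0014
SG0085	SG0068
SG0101	SG0019
SG0077	SG0063
SG0032	SG0107
SG0021	SG0063
SG0052	SG0036
SG0093	SG0104
SG0115	SG0087
SG0107	SG0027
SG0100	SG0117
SG0002	SG0110
SG0020	SG0088
SG0058	SG0049
SG0005	SG0080
SG0115	SG0014
SG0065	SG0075
SG0057	SG0026
SG0098	SG0043
SG0004	SG0111
SG0072	SG0027
SG0098	SG0072
SG0013	SG0083
SG0098	SG0033
SG0018	SG0113
SG0076	SG0108
SG0016	SG0041
SG0050	SG0029
SG0022	SG0060
SG0011	SG0099
SG0020	SG0018
SG0109	SG0002
SG0086	SG0064
SG0102	SG0103
SG0045	SG0113
SG0064	SG0102
SG0084	SG0053
SG0045	SG0100
SG0093	SG0044
SG0050	SG0022
SG0007	SG0117
SG0055	SG0061
SG0082	SG0029
SG0013	SG0027
SG0035	SG0070
SG0079	SG0113
SG0032	SG0025
SG0062	SG0066
SG0067	SG0102
SG0012	SG0106
SG0064	SG0079
SG0008	SG0112
SG0048	SG0064
SG0019	SG0117
SG0094	SG0037
SG0056	SG0075
SG0102	SG0020
SG0036	SG0043
SG0010	SG0102
SG0110	SG0063
SG0118	SG0084
SG0017	SG0037
SG0088	SG0027
SG0093	SG0075
SG0111	SG0106
SG0050	SG0035
SG0115	SG0077
SG0097	SG0046
SG0040	SG0015
SG0024	SG0073
SG0028	SG0050
SG0114	SG0050
SG0104	SG0119
SG0102	SG0017
SG0002	SG0087
SG0114	SG0052
SG0035	SG0078
SG0025	SG0098
SG0006	SG0012
SG0031	SG0017
SG0061	SG0013
SG0092	SG0009
SG0101	SG0037
SG0033	SG0039
SG0010	SG0090
SG0022	SG0024
SG0007	SG0108
SG0002	SG0035
SG0054	SG0056
SG0039	SG0054
SG0048	SG0058
SG0053	SG0067
SG0049	SG0067
SG0109	SG0089
SG0088	SG0021
SG0063	SG0098
SG0063	SG0115
SG0009	SG0072
SG0008	SG0065
SG0013	SG0104
SG0067	SG0020
SG0019	SG0114
SG0078	SG0077
SG0104	SG0042
SG0055	SG0000
SG0119	SG0061
SG0111	SG0067
SG0056	SG0055
SG0113	SG0109
SG0052	SG0079
SG0010	SG0087
SG0010	SG0041
SG0023	SG0119
SG0073	SG0005
SG0029	SG0100
SG0049	SG0080
SG0065	SG0059
SG0096	SG0051
SG0074	SG0054
SG0070	SG0018
SG0049	SG0027
SG0053	SG0036
SG0067	SG0118
SG0062	SG0072
SG0030	SG0002
SG0085	SG0075
SG0075	SG0110
SG0050	SG0090
SG0106	SG0115
SG0089	SG0074
SG0090	SG0063
SG0075	SG0017
SG0060	SG0103
SG0054	SG0045
SG0107	SG0098
SG0046	SG0001
SG0102	SG0105
SG0118	SG0081
SG0098	SG0100
SG0086	SG0034
SG0063	SG0078
SG0024	SG0016
SG0064	SG0062
SG0054	SG0101
SG0062	SG0082
SG0008	SG0076
SG0105	SG0034
SG0007	SG0085
SG0041	SG0107
SG0034	SG0021
SG0104	SG0056
SG0011	SG0055
SG0006	SG0041
SG0012	SG0025
SG0027	SG0017
SG0116	SG0017
SG0116	SG0090
SG0117	SG0011
SG0110	SG0107
SG0056	SG0038
SG0099	SG0064
SG0080	SG0116
SG0101	SG0115
SG0066	SG0115
SG0046	SG0104
SG0072	SG0046
SG0035	SG0066
SG0054	SG0008
SG0109	SG0003
SG0056	SG0057
SG0086	SG0054
SG0088	SG0002
SG0044	SG0077
SG0116	SG0056
SG0038	SG0112
SG0087	SG0082
SG0070	SG0043
SG0034	SG0028
SG0060	SG0067
SG0057	SG0068
SG0074	SG0109
SG0033	SG0029
SG0098	SG0079
SG0050	SG0016
SG0024	SG0111
SG0022	SG0016
SG0074	SG0047
SG0034	SG0066
SG0074	SG0086
SG0037	SG0031
SG0089	SG0086
SG0034	SG0079
SG0092	SG0087
SG0005	SG0034
SG0094	SG0020
SG0027	SG0087
SG0038	SG0117
SG0099	SG0105
SG0033	SG0000
SG0022	SG0064
SG0025	SG0103
SG0078	SG0114
SG0059	SG0034
SG0007	SG0112
SG0040	SG0052
SG0058	SG0015
SG0057	SG0103
SG0056	SG0000
SG0027	SG0024
SG0104	SG0061
SG0074	SG0056
SG0115	SG0116
SG0098	SG0104
SG0116	SG0039
SG0100	SG0040
SG0058	SG0103
SG0098	SG0068
SG0083	SG0115
SG0021	SG0070
SG0079	SG0002
SG0071	SG0064
SG0001	SG0023
SG0030	SG0078
SG0011	SG0060
SG0077	SG0030
SG0002	SG0051
SG0066	SG0013
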