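#rank	taxon	parent_taxon	marker_sets
domain	Bacteria	root	[[MB0001,MB0002,MB0003,MB0004,MB0005],[MB0006,MB0007,MB0008,MB0009,MB0010],[MB0011,MB0012,MB0013,MB0014,MB0015],[MB0016,MB0017,MB0018,MB0019,MB0020],[MB0021,MB0022,MB0023,MB0024,MB0025],[MB0026,MB0027,MB0028,MB0029,MB0030],[MB0031,MB0032,MB0033,MB0034,MB0035],[MB0036,MB0037,MB0038,MB0039,MB0040],[MB0041,MB0042,MB0043,MB0044,MB0045],[MB0046,MB0047,MB0048,MB0049,MB0050],[MB0051,MB0052,MB0053,MB0054,MB0055],[MB0056,MB0057,MB0058,MB0059,MB0060],[MB0061,MB0062,MB0063,MB0064,MB0065],[MB0066,MB0067,MB0068,MB0069,MB0070],[MB0071,MB0072,MB0073,MB0074,MB0075],[MB0076,MB0077,MB0078,MB0079,MB0080],[MB0081,MB0082,MB0083,MB0084,MB0085],[MB0086,MB0087,MB0088,MB0089,MB0090],[MB0091,MB0092,MB0093,MB0094,MB0095],[MB0096,MB0097,MB0098,MB0099,MB0100],[MB0101,MB0102,MB0103,MB0104,MB0105],[MB0106,MB0107,MB0108,MB0109,MB0110],[MB0111,MB0112,MB0113,MB0114,MB0115],[MB0116,MB0117,MB0118,MB0119,MB0120]]
phylum	Proteobacteria	Bacteria	[[MB0121,MB0122,MB0123,MB0124],[MB0125,MB0126,MB0127,MB0128],[MB0129,MB0130,MB0131,MB0132],[MB0133,MB0134,MB0135,MB0136],[MB0137,MB0138,MB0139,MB0140],[MB0141,MB0142,MB0143,MB0144],[MB0145,MB0146,MB0147,MB0148],[MB0149,MB0150,MB0151,MB0152],[MB0153,MB0154,MB0155,MB0156],[MB0157,MB0158,MB0159,MB0160]]
class	Alphaproteobacteria	Proteobacteria	[[MB0161,MB0162,MB0163,MB0164],[MB0165,MB0166,MB0167,MB0168],[MB0169,MB0170,MB0171,MB0172],[MB0173,MB0174,MB0175,MB0176],[MB0177,MB0178,MB0179,MB0180],[MB0181,MB0182,MB0183,MB0184],[MB0185,MB0186,MB0187,MB0188],[MB0189,MB0190,MB0191,MB0192]]
class	Gammaproteobacteria	Proteobacteria	[[MB0193,MB0194,MB0195,MB0196],[MB0197,MB0198,MB0199,MB0200],[MB0201,MB0202,MB0203,MB0204],[MB0205,MB0206,MB0207,MB0208],[MB0209,MB0210,MB0211,MB0212],[MB0213,MB0214,MB0215,MB0216],[MB0217,MB0218,MB0219,MB0220],[MB0221,MB0222,MB0223,MB0224]]
phylum	Firmicutes	Bacteria	[[MB0225,MB0226,MB0227,MB0228],[MB0229,MB0230,MB0231,MB0232],[MB0233,MB0234,MB0235,MB0236],[MB0237,MB0238,MB0239,MB0240],[MB0241,MB0242,MB0243,MB0244],[MB0245,MB0246,MB0247,MB0248],[MB0249,MB0250,MB0251,MB0252],[MB0253,MB0254,MB0255,MB0256],[MB0257,MB0258,MB0259,MB0260],[MB0261,MB0262,MB0263,MB0264]]
class	Bacilli	Firmicutes	[[MB0265,MB0266,MB0267,MB0268],[MB0269,MB0270,MB0271,MB0272],[MB0273,MB0274,MB0275,MB0276],[MB0277,MB0278,MB0279,MB0280],[MB0281,MB0282,MB0283,MB0284],[MB0285,MB0286,MB0287,MB0288],[MB0289,MB0290,MB0291,MB0292],[MB0293,MB0294,MB0295,MB0296]]
class	Clostridia	Firmicutes	[[MB0297,MB0298,MB0299,MB0300],[MB0301,MB0302,MB0303,MB0304],[MB0305,MB0306,MB0307,MB0308],[MB0309,MB0310,MB0311,MB0312],[MB0313,MB0314,MB0315,MB0316],[MB0317,MB0318,MB0319,MB0320],[MB0321,MB0322,MB0323,MB0324],[MB0325,MB0326,MB0327,MB0328]]
domain	Archaea	root	[[MA0001,MA0002,MA0003,MA0004],[MA0005,MA0006,MA0007,MA0008],[MA0009,MA0010,MA0011,MA0012],[MA0013,MA0014,MA0015,MA0016],[MA0017,MA0018,MA0019,MA0020],[MA0021,MA0022,MA0023,MA0024],[MA0025,MA0026,MA0027,MA0028],[MA0029,MA0030,MA0031,MA0032],[MA0033,MA0034,MA0035,MA0036],[MA0037,MA0038,MA0039,MA0040],[MA0041,MA0042,MA0043,MA0044],[MA0045,MA0046,MA0047,MA0048],[MA0049,MA0050,MA0051,MA0052],[MA0053,MA0054,MA0055,MA0056],[MA0057,MA0058,MA0059,MA0060],[MA0061,MA0062,MA0063,MA0064],[MA0065,MA0066,MA0067,MA0068],[MA0069,MA0070,MA0071,MA0072],[MA0073,MA0074,MA0075,MA0076],[MA0077,MA0078,MA0079,MA0080]]
phylum	Euryarchaeota	Archaea	[[MA0081,MA0082,MA0083,MA0084],[MA0085,MA0086,MA0087,MA0088],[MA0089,MA0090,MA0091,MA0092],[MA0093,MA0094,MA0095,MA0096],[MA0097,MA0098,MA0099,MA0100],[MA0101,MA0102,MA0103,MA0104],[MA0105,MA0106,MA0107,MA0108],[MA0109,MA0110,MA0111,MA0112]]
class	Methanomicrobia	Euryarchaeota	[[MA0113,MA0114,MA0115,MA0116],[MA0117,MA0118,MA0119,MA0120],[MA0121,MA0122,MA0123,MA0124],[MA0125,MA0126,MA0127,MA0128],[MA0129,MA0130,MA0131,MA0132],[MA0133,MA0134,MA0135,MA0136],[MA0137,MA0138,MA0139,MA0140],[MA0141,MA0142,MA0143,MA0144]]
phylum	Crenarchaeota	Archaea	[[MA0145,MA0146,MA0147,MA0148],[MA0149,MA0150,MA0151,MA0152],[MA0153,MA0154,MA0155,MA0156],[MA0157,MA0158,MA0159,MA0160],[MA0161,MA0162,MA0163,MA0164],[MA0165,MA0166,MA0167,MA0168],[MA0169,MA0170,MA0171,MA0172],[MA0173,MA0174,MA0175,MA0176]]
class	Thermoprotei	Crenarchaeota	[[MA0177,MA0178,MA0179,MA0180],[MA0181,MA0182,MA0183,MA0184],[MA0185,MA0186,MA0187,MA0188],[MA0189,MA0190,MA0191,MA0192],[MA0193,MA0194,MA0195,MA0196],[MA0197,MA0198,MA0199,MA0200],[MA0201,MA0202,MA0203,MA0204],[MA0205,MA0206,MA0207,MA0208]]
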