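# generic name -> heart-disease-related category
lisinopril	ACE inhibitors
enalapril	ACE inhibitors
captopril	ACE inhibitors
ramipril	ACE inhibitors
benazepril	ACE inhibitors
quinapril	ACE inhibitors
fosinopril	ACE inhibitors
losartan	ARBs
valsartan	ARBs
irbesartan	ARBs
candesartan	ARBs
olmesartan	ARBs
telmisartan	ARBs
pramlintide	amylin
acarbose	antidiabetes medications
miglitol	antidiabetes medications
bromocriptine	antidiabetes medications
colesevelam	antidiabetes medications
aspirin	aspirin
metoprolol	beta-blockers
atenolol	beta-blockers
carvedilol	beta-blockers
propranolol	beta-blockers
labetalol	beta-blockers
bisoprolol	beta-blockers
nadolol	beta-blockers
amlodipine	calcium-channel blockers
diltiazem	calcium-channel blockers
verapamil	calcium-channel blockers
nifedipine	calcium-channel blockers
felodipine	calcium-channel blockers
nicardipine	calcium-channel blockers
sitagliptin	DPP-4 inhibitors
saxagliptin	DPP-4 inhibitors
linagliptin	DPP-4 inhibitors
alogliptin	DPP-4 inhibitors
vildagliptin	DPP-4 inhibitors
ezetimibe	ezetimibe
gemfibrozil	fibrates
fenofibrate	fibrates
clofibrate	fibrates
bezafibrate	fibrates
exenatide	GLP-1 agonists
liraglutide	GLP-1 agonists
dulaglutide	GLP-1 agonists
semaglutide	GLP-1 agonists
lixisenatide	GLP-1 agonists
insulin	insulin
insulin glargine	insulin
insulin lispro	insulin
insulin aspart	insulin
insulin detemir	insulin
nph insulin	insulin
repaglinide	meglitinides
nateglinide	meglitinides
metformin	metformin
niacin	niacin
nicotinic acid	niacin
nitroglycerin	nitrates
isosorbide mononitrate	nitrates
isosorbide dinitrate	nitrates
atorvastatin	statins
simvastatin	statins
pravastatin	statins
rosuvastatin	statins
lovastatin	statins
fluvastatin	statins
pitavastatin	statins
glyburide	sulfonylureas
glipizide	sulfonylureas
glimepiride	sulfonylureas
chlorpropamide	sulfonylureas
tolbutamide	sulfonylureas
hydrochlorothiazide	thiazide diuretics
chlorthalidone	thiazide diuretics
indapamide	thiazide diuretics
metolazone	thiazide diuretics
pioglitazone	thiazolidinediones
rosiglitazone	thiazolidinediones
troglitazone	thiazolidinediones
clopidogrel	thienopyridines
ticlopidine	thienopyridines
prasugrel	thienopyridines
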