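publication_type	low_level_category	broad_category	manual
Case-Control Studies	Observational Epidemiologic Study Designs	Observational Clinical Research	0
Cross-Sectional Studies	Observational Epidemiologic Study Designs	Observational Clinical Research	0
Longitudinal Studies	Observational Epidemiologic Study Designs	Observational Clinical Research	0
Cohort Studies	Observational Epidemiologic Study Designs	Observational Clinical Research	0
Retrospective Studies	Observational Epidemiologic Study Designs	Observational Clinical Research	0
Multicentre Study	General Clinical & Observational Studies	Observational Clinical Research	0
Clinical Study	General Clinical & Observational Studies	Observational Clinical Research	0
Prospective Studies	General Clinical & Observational Studies	Observational Clinical Research	0
Follow-Up Studies	General Clinical & Observational Studies	Observational Clinical Research	0
Observational Study	General Clinical & Observational Studies	Observational Clinical Research	0
Cross-Cultural Comparison	Qualitative & Sociocultural Research Methods	Qualitative & Genetic Methods	0
Focus Groups	Qualitative & Sociocultural Research Methods	Qualitative & Genetic Methods	0
Interviews as Topic	Qualitative & Sociocultural Research Methods	Qualitative & Genetic Methods	0
Genome-Wide Association Study	Genetic & Matched Population Analyses	Qualitative & Genetic Methods	0
Matched-Pair Analysis	Genetic & Matched Population Analyses	Qualitative & Genetic Methods	0
Twin Study	Genetic & Matched Population Analyses	Qualitative & Genetic Methods	0
Case Reports	Clinical Case-Based Evidence	Clinical Evaluation & Validation	0
Case Series	Clinical Case-Based Evidence	Clinical Evaluation & Validation	0
Diagnostic Test Accuracy	Diagnostic & Methodological Validation Studies	Clinical Evaluation & Validation	0
Predictive Value of Tests	Diagnostic & Methodological Validation Studies	Clinical Evaluation & Validation	0
Reproducibility of Results	Diagnostic & Methodological Validation Studies	Clinical Evaluation & Validation	0
Validation Study	Diagnostic & Methodological Validation Studies	Clinical Evaluation & Validation	0
Evaluation Studies as Topic	Program & Process Evaluation Studies	Clinical Evaluation & Validation	0
Evaluation Study	Program & Process Evaluation Studies	Clinical Evaluation & Validation	0
Feasibility Studies	Program & Process Evaluation Studies	Clinical Evaluation & Validation	0
Clinical Trial, Phase I	Interventional Clinical Trial Phases & Designs	Interventional Trial Research	0
Clinical Trial, Phase II	Interventional Clinical Trial Phases & Designs	Interventional Trial Research	0
Clinical Trial, Phase III	Interventional Clinical Trial Phases & Designs	Interventional Trial Research	0
Clinical Trial, Phase IV	Interventional Clinical Trial Phases & Designs	Interventional Trial Research	0
Clinical Trial Protocol	Interventional Clinical Trial Phases & Designs	Interventional Trial Research	0
Pragmatic Clinical Trial	Interventional Clinical Trial Phases & Designs	Interventional Trial Research	0
Adaptive Clinical Trial	Interventional Clinical Trial Phases & Designs	Interventional Trial Research	0
Equivalence Trial	Interventional Clinical Trial Phases & Designs	Interventional Trial Research	0
Clinical Trial, Veterinary	Controlled & Randomized Trial Methodology	Interventional Trial Research	0
Randomized Controlled Trial, Veterinary	Controlled & Randomized Trial Methodology	Interventional Trial Research	0
Cross-Over Studies	Controlled & Randomized Trial Methodology	Interventional Trial Research	0
Double-Blind Method	Controlled & Randomized Trial Methodology	Interventional Trial Research	0
Clinical Trial	Controlled & Randomized Trial Methodology	Interventional Trial Research	0
Controlled Clinical Trial	Controlled & Randomized Trial Methodology	Interventional Trial Research	0
Random Allocation	Controlled & Randomized Trial Methodology	Interventional Trial Research	0
Randomized Controlled Trial	Controlled & Randomized Trial Methodology	Interventional Trial Research	0
Practice Guidelines as Topic	Evidence Synthesis & Clinical Guidance	Scholarly Discourse and Evidence Synthesis	0
Review	Evidence Synthesis & Clinical Guidance	Scholarly Discourse and Evidence Synthesis	0
Systematic Review	Evidence Synthesis & Clinical Guidance	Scholarly Discourse and Evidence Synthesis	0
Meta-Analysis	Evidence Synthesis & Clinical Guidance	Scholarly Discourse and Evidence Synthesis	0
Meta-Analysis as Topic	Evidence Synthesis & Clinical Guidance	Scholarly Discourse and Evidence Synthesis	0
Systematic Reviews as Topic	Evidence Synthesis & Clinical Guidance	Scholarly Discourse and Evidence Synthesis	0
Practice Guideline	Evidence Synthesis & Clinical Guidance	Scholarly Discourse and Evidence Synthesis	0
Congress	Evidence Synthesis & Clinical Guidance	Scholarly Discourse and Evidence Synthesis	0
Consensus Development Conference	Evidence Synthesis & Clinical Guidance	Scholarly Discourse and Evidence Synthesis	0
News	Scientific Commentary & Professional Discourse	Scholarly Discourse and Evidence Synthesis	0
Letter	Scientific Commentary & Professional Discourse	Scholarly Discourse and Evidence Synthesis	0
Comment	Scientific Commentary & Professional Discourse	Scholarly Discourse and Evidence Synthesis	0
Editorial	Scientific Commentary & Professional Discourse	Scholarly Discourse and Evidence Synthesis	0
Clinical Conference	Scientific Commentary & Professional Discourse	Scholarly Discourse and Evidence Synthesis	0
Lecture	Scientific Commentary & Professional Discourse	Scholarly Discourse and Evidence Synthesis	0
Legal Case	Biographical, Historical & Narrative Works	Scholarly Discourse and Evidence Synthesis	0
Portrait	Biographical, Historical & Narrative Works	Scholarly Discourse and Evidence Synthesis	0
Biography	Biographical, Historical & Narrative Works	Scholarly Discourse and Evidence Synthesis	0
Historical Article	Biographical, Historical & Narrative Works	Scholarly Discourse and Evidence Synthesis	0
Interview	Biographical, Historical & Narrative Works	Scholarly Discourse and Evidence Synthesis	0
Autobiography	Biographical, Historical & Narrative Works	Scholarly Discourse and Evidence Synthesis	0
Personal Narrative	Biographical, Historical & Narrative Works	Scholarly Discourse and Evidence Synthesis	0
Clinical Studies as Topic	Scholarly Publishing & Research Integrity	Scholarly Discourse and Evidence Synthesis	0
Clinical Trials As Topic	Scholarly Publishing & Research Integrity	Scholarly Discourse and Evidence Synthesis	0
Human Experimentation	Scholarly Publishing & Research Integrity	Scholarly Discourse and Evidence Synthesis	0
Newspaper Article	Scholarly Publishing & Research Integrity	Scholarly Discourse and Evidence Synthesis	0
Bibliography	Scholarly Publishing & Research Integrity	Scholarly Discourse and Evidence Synthesis	0
Expression of Concern	Scholarly Publishing & Research Integrity	Scholarly Discourse and Evidence Synthesis	0
Published Erratum	Scholarly Publishing & Research Integrity	Scholarly Discourse and Evidence Synthesis	0
Retraction of Publication	Scholarly Publishing & Research Integrity	Scholarly Discourse and Evidence Synthesis	0
Scientific Integrity Review	Scholarly Publishing & Research Integrity	Scholarly Discourse and Evidence Synthesis	1
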