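Case-Control Studies
Cross-Sectional Studies
Longitudinal Studies
Cohort Studies
Retrospective Studies
Multicentre Study
Clinical Study
Prospective Studies
Follow-Up Studies
Observational Study
Cross-Cultural Comparison
Focus Groups
Interviews as Topic
Genome-Wide Association Study
Matched-Pair Analysis
Twin Study
Case Reports
Case Series
Diagnostic Test Accuracy
Predictive Value of Tests
Reproducibility of Results
Validation Study
Evaluation Studies as Topic
Evaluation Study
Feasibility Studies
Clinical Trial, Phase I
Clinical Trial, Phase II
Clinical Trial, Phase III
Clinical Trial, Phase IV
Clinical Trial Protocol
Pragmatic Clinical Trial
Adaptive Clinical Trial
Equivalence Trial
Clinical Trial, Veterinary
Randomized Controlled Trial, Veterinary
Cross-Over Studies
Double-Blind Method
Clinical Trial
Controlled Clinical Trial
Random Allocation
Randomized Controlled Trial
Practice Guidelines as Topic
Review
Systematic Review
Meta-Analysis
Meta-Analysis as Topic
Systematic Reviews as Topic
Practice Guideline
Congress
Consensus Development Conference
News
Letter
Comment
Editorial
Clinical Conference
Lecture
Legal Case
Portrait
Biography
Historical Article
Interview
Autobiography
Personal Narrative
Clinical Studies as Topic
Clinical Trials As Topic
Human Experimentation
Newspaper Article
Bibliography
Expression of Concern
Published Erratum
Retraction of Publication
Scientific Integrity Review
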