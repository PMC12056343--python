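#!/usr/bin/env Rscript
# Generic JAGS runner: model file + JSON data/inits in, stacked draws CSV out.
# Usage: Rscript jags_driver.R model.txt data.json inits.json params.txt \
#          n_adapt n_burn n_iter thin out.csv
suppressMessages({
  library(rjags)
  library(jsonlite)
  load.module("glm", quiet = TRUE)
})

args <- commandArgs(trailingOnly = TRUE)
model_file <- args[1]
data <- fromJSON(args[2])
inits <- fromJSON(args[3], simplifyDataFrame = FALSE, simplifyMatrix = FALSE)
params <- scan(args[4], what = character(), quiet = TRUE)
n_adapt <- as.integer(args[5])
n_burn <- as.integer(args[6])
n_iter <- as.integer(args[7])
thin <- as.integer(args[8])
out_csv <- args[9]

# jsonlite returns lists for init vectors; coerce numerics, keep RNG fields
inits <- lapply(inits, function(chain) {
  lapply(chain, function(v) {
    if (is.list(v)) v <- unlist(v)
    if (is.character(v)) v else as.numeric(v)
  })
})
for (i in seq_along(inits)) {
  inits[[i]][[".RNG.name"]] <- "base::Mersenne-Twister"
  inits[[i]][[".RNG.seed"]] <- as.integer(inits[[i]][[".RNG.seed"]])
}

model <- jags.model(
  model_file, data = data, inits = inits,
  n.chains = length(inits), n.adapt = n_adapt, quiet = TRUE
)
update(model, n_burn, progress.bar = "none")
samples <- coda.samples(model, variable.names = params, n.iter = n_iter,
                        thin = thin, progress.bar = "none")

mats <- lapply(seq_along(samples), function(i) {
  m <- as.matrix(samples[[i]])
  cbind(chain = i, as.data.frame(m))
})
write.csv(do.call(rbind, mats), out_csv, row.names = FALSE)
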